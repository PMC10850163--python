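import numpy as np
import pytest

from lociforge.io_formats import GenotypePanel
from lociforge.ld_clump import (RiskLocus, SnpClassification, Thresholds,
                                classify_snps, compute_r2, define_risk_loci,
                                ld_block)


class TestComputeR2:
    def test_identical_columns_give_one(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        panel = GenotypePanel(["a", "b"], ["1", "1"], np.array([1, 2]),
                              np.column_stack([col, col]))
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        b = np.array([2, 2, 1, 1, 0, 0], dtype=float)
        panel = GenotypePanel(["a", "b"], ["1", "1"], np.array([1, 2]),
                              np.column_stack([a, b]))
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_orthogonal_dosage_vectors_give_zero(self):
        # Pearson correlation over the six pairs is exactly 0
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        b = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        panel = GenotypePanel(["a", "b"], ["1", "1"], np.array([1, 2]),
                              np.column_stack([a, b]))
        assert compute_r2(panel, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_snp_is_unlinkable(self, caplog):
        a = np.array([1, 1, 1, 1], dtype=float)
        b = np.array([0, 1, 2, 0], dtype=float)
        panel = GenotypePanel(["a", "b"], ["1", "1"], np.array([1, 2]),
                              np.column_stack([a, b]))
        import logging
        with caplog.at_level(logging.WARNING):
            assert compute_r2(panel, "a", "b") == 0.0
        assert "monomorphic" in caplog.text

    def test_absent_snp_is_error(self, tiny_panel):
        with pytest.raises(KeyError):
            compute_r2(tiny_panel, "s1", "nope")


class TestClassifySnps:
    def test_single_significant_snp_occupies_all_tiers(self, tiny_panel, stat_factory):
        stats = [stat_factory("s1", "1", 1000, 1e-10),
                 stat_factory("s3", "1", 500_000, 0.5)]
        c = classify_snps(stats, tiny_panel)
        assert c.significant == ["s1"]
        assert c.independent_significant == ["s1"] and c.leads == ["s1"]
        assert c.is_candidate("s1")

    def test_no_significant_snps_gives_empty_tiers(self, tiny_panel, stat_factory):
        stats = [stat_factory("s1", "1", 1000, 1e-4)]
        c = classify_snps(stats, tiny_panel)
        assert c.independent_significant == [] and c.leads == []
        assert c.candidates == {}
        assert define_risk_loci(c) == []

    def test_three_snp_greedy_instance(self, tiny_panel, stat_factory):
        # s3 strongest, weakly linked to both; s1 and s2 tightly linked
        r2_12 = compute_r2(tiny_panel, "s1", "s2")
        assert r2_12 > 0.8
        assert compute_r2(tiny_panel, "s1", "s3") < 0.1
        stats = [stat_factory("s1", "1", 1000, 1e-10),
                 stat_factory("s2", "1", 2000, 1e-9),
                 stat_factory("s3", "1", 500_000, 1e-12)]
        c = classify_snps(stats, tiny_panel)
        assert c.independent_significant == ["s3", "s1"]
        assert c.leads == ["s3", "s1"]
        assert set(c.candidates) == {"s1", "s2", "s3"}
        # s2 is tagged by s1, not accepted as independent
        assert [i for i, _ in c.candidates["s2"]] == ["s1"]

    def test_significant_snp_absent_from_panel_kept_as_singleton(
            self, tiny_panel, stat_factory, caplog):
        import logging
        stats = [stat_factory("ghost", "9", 42, 1e-20)]
        with caplog.at_level(logging.WARNING):
            c = classify_snps(stats, tiny_panel)
        assert c.independent_significant == ["ghost"]
        assert c.candidates["ghost"] == [("ghost", 1.0)]
        assert "absent from the reference panel" in caplog.text

    def test_candidate_count_monotone_in_significance_threshold(
            self, tiny_panel, stat_factory):
        stats = [stat_factory("s1", "1", 1000, 1e-9),
                 stat_factory("s2", "1", 2000, 1e-6),
                 stat_factory("s3", "1", 500_000, 1e-7)]
        loose = classify_snps(stats, tiny_panel, Thresholds(p_gw=1e-5))
        strict = classify_snps(stats, tiny_panel, Thresholds(p_gw=5e-8))
        assert len(loose.candidates) >= len(strict.candidates)


def make_classification(indep, positions, candidates, indep_r2, chrom="1",
                        leads=None):
    ids = sorted(set(positions))
    return SnpClassification(
        significant=list(indep),
        independent_significant=list(indep),
        leads=list(leads if leads is not None else indep),
        candidates=candidates,
        snp_chrom={s: chrom for s in ids},
        snp_pos=dict(positions),
        snp_p={s: 1e-9 for s in ids},
        indep_r2=np.asarray(indep_r2, dtype=float),
    )


class TestLdBlockAndLoci:
    def test_self_tagging_block_is_single_position(self):
        c = make_classification(["a"], {"a": 1000}, {"a": [("a", 1.0)]}, [[1.0]])
        assert ld_block(c, "a") == ("1", 1000, 1000)

    def test_block_span_is_min_max_of_tags(self):
        cands = {"a": [("a", 1.0)], "x": [("a", 0.9)], "y": [("a", 0.85)]}
        c = make_classification(["a"], {"a": 1000, "x": 1500, "y": 1200}, cands,
                                [[1.0]])
        assert ld_block(c, "a") == ("1", 1000, 1500)

    def test_shared_candidate_appears_in_both_blocks(self):
        cands = {"a": [("a", 1.0)],
                 "b": [("b", 1.0)],
                 "m": [("a", 0.9), ("b", 0.9)]}
        c = make_classification(["a", "b"], {"a": 100, "b": 900, "m": 500},
                                cands, [[1.0, 0.05], [0.05, 1.0]])
        assert ld_block(c, "a") == ("1", 100, 500)
        assert ld_block(c, "b") == ("1", 500, 900)

    def test_blocks_closer_than_merge_gap_join_one_locus(self):
        cands = {"a": [("a", 1.0)], "a2": [("a", 0.9)],
                 "b": [("b", 1.0)], "b2": [("b", 0.9)]}
        pos = {"a": 1_000, "a2": 50_000, "b": 200_000, "b2": 260_000}
        c = make_classification(["a", "b"], pos, cands,
                                [[1.0, 0.01], [0.01, 1.0]])
        loci = define_risk_loci(c)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1_000, 260_000)

    def test_distant_uncorrelated_blocks_stay_separate(self):
        cands = {"a": [("a", 1.0)], "b": [("b", 1.0)]}
        pos = {"a": 1_000, "b": 301_001}
        c = make_classification(["a", "b"], pos, cands,
                                [[1.0, 0.02], [0.02, 1.0]])
        loci = define_risk_loci(c)
        assert len(loci) == 2

    def test_merge_is_transitive_across_a_chain(self):
        cands = {"a": [("a", 1.0)], "b": [("b", 1.0)], "c": [("c", 1.0)]}
        pos = {"a": 1_000, "b": 201_000, "c": 401_000}   # a-b and b-c gaps 200 kb
        r2 = np.full((3, 3), 0.01)
        np.fill_diagonal(r2, 1.0)
        c = make_classification(["a", "b", "c"], pos, cands, r2)
        loci = define_risk_loci(c)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1_000, 401_000)
        assert set(loci[0].independent_significant_ids) == {"a", "b", "c"}

    def test_correlated_blocks_merge_despite_distance(self):
        cands = {"a": [("a", 1.0)], "b": [("b", 1.0)]}
        pos = {"a": 1_000, "b": 2_000_000}
        c = make_classification(["a", "b"], pos, cands,
                                [[1.0, 0.15], [0.15, 1.0]], leads=["a"])
        loci = define_risk_loci(c)
        assert len(loci) == 1 and loci[0].lead_snp_ids == ("a",)

    def test_no_final_locus_pair_satisfies_merge_condition(self):
        rng = np.random.default_rng(7)
        n = 12
        pos = {f"i{k}": int(p) for k, p in
               enumerate(np.sort(rng.integers(1, 3_000_000, n)))}
        cands = {s: [(s, 1.0)] for s in pos}
        r2 = np.zeros((n, n))
        np.fill_diagonal(r2, 1.0)
        c = make_classification(list(pos), pos, cands, r2)
        loci = define_risk_loci(c)
        th = Thresholds()
        for i, l1 in enumerate(loci):
            for l2 in loci[i + 1:]:
                if l1.chrom == l2.chrom:
                    gap = max(l1.start, l2.start) - min(l1.end, l2.end)
                    assert gap >= th.merge_gap_bp
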