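import numpy as np
import pytest
from scipy import stats as sps

from lociforge.ld_clump import Thresholds, classify_snps, define_risk_loci
from lociforge.locus_annotation import pqtl_near_leads
from lociforge.synthetic_data import (BlockSpec, DEGConfig, PlantedLocus,
                                      SCConfig, SimConfig, SimTruth,
                                      simulate_annotations, simulate_cell_matrix,
                                      simulate_deg_tables, simulate_panel,
                                      simulate_summary_stats, snp_metadata,
                                      write_all)


def small_config(**kw):
    defaults = dict(
        seed=11, n_samples_panel=300, n_gwas_cohort=800,
        blocks=(BlockSpec(n_snps=10),) * 3,
        planted_loci=(PlantedLocus(block=0, causal_index=5, beta=0.5),),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPanelLd:
    def test_rho_one_block_is_perfectly_correlated(self):
        cfg = small_config(blocks=(BlockSpec(n_snps=5, rho=1.0),),
                           planted_loci=())
        panel = simulate_panel(cfg)
        r = np.corrcoef(panel.dosages.T)
        assert np.allclose(r**2, 1.0)

    def test_rho_zero_block_is_uncorrelated(self):
        cfg = small_config(n_samples_panel=500,
                           blocks=(BlockSpec(n_snps=30, rho=0.0),),
                           planted_loci=())
        panel = simulate_panel(cfg)
        r = np.corrcoef(panel.dosages.T)
        adjacent = np.array([r[i, i + 1]**2 for i in range(29)])
        assert adjacent.mean() < 0.05

    def test_adjacent_r2_matches_independent_resimulation(self):
        """ρ=0.9 adjacent dosage r² agrees within ±0.1 between two seeds."""
        def mean_adj_r2(seed):
            cfg = small_config(seed=seed, n_samples_panel=2000,
                               blocks=(BlockSpec(n_snps=40, rho=0.9),),
                               planted_loci=())
            panel = simulate_panel(cfg)
            r = np.corrcoef(panel.dosages.T)
            return np.mean([r[i, i + 1]**2 for i in range(39)])

        assert abs(mean_adj_r2(1) - mean_adj_r2(99)) < 0.1

    def test_blocks_are_independent(self):
        cfg = small_config(n_samples_panel=2000,
                           blocks=(BlockSpec(n_snps=5, rho=1.0),) * 2,
                           planted_loci=())
        panel = simulate_panel(cfg)
        r2 = np.corrcoef(panel.dosages[:, 0], panel.dosages[:, 5])[0, 1]**2
        assert r2 < 0.05


class TestSummaryStats:
    def test_null_p_values_are_uniform(self):
        cfg = SimConfig(seed=5, n_samples_panel=50, n_gwas_cohort=500,
                        blocks=tuple(BlockSpec(n_snps=20, rho=0.0)
                                     for _ in range(250)),
                        planted_loci=())
        stats, _ = simulate_summary_stats(cfg)
        assert len(stats) == 5000
        ks = sps.kstest([r.p for r in stats], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_causal_snp_reaches_significance(self):
        """β chosen for expected P << 5e-8 is significant in >=99/100 runs."""
        hits = 0
        for rep in range(100):
            cfg = SimConfig(seed=20_000 + rep, n_samples_panel=100,
                            n_gwas_cohort=5000,
                            blocks=(BlockSpec(n_snps=10),),
                            planted_loci=(PlantedLocus(0, 5, beta=0.3),))
            stats, truth = simulate_summary_stats(cfg)
            p = {r.snp_id: r.p for r in stats}
            hits += p[truth.causal_snp_ids[0]] < 5e-8
        assert hits >= 99

    def test_fixed_seed_reproduces_records_exactly(self):
        cfg = small_config()
        s1, _ = simulate_summary_stats(cfg)
        s2, _ = simulate_summary_stats(cfg)
        assert s1 == s2


class TestAnnotations:
    def test_planted_eqtl_below_cutoff_and_decoys_above(self):
        cfg = small_config()
        _, truth = simulate_summary_stats(cfg)
        ann = simulate_annotations(cfg, truth)
        planted = ann.eqtl[ann.eqtl["gene_id"].isin(
            truth.planted_genes["eqtl"])]
        assert (planted["fdr"] < 0.05).all()
        decoys = ann.eqtl[ann.eqtl["gene_id"].str.startswith("decoy_eqtl")]
        assert (decoys["fdr"] >= 0.05).all()

    def test_decoy_interactions_fail_fdr_cutoff(self):
        cfg = small_config()
        _, truth = simulate_summary_stats(cfg)
        ann = simulate_annotations(cfg, truth)
        assert (ann.interactions["fdr"] < 1e-6).sum() == len(
            truth.planted_genes["chromatin"])

    def test_pqtl_window_arithmetic(self):
        """A pQTL 19,999 bp from a lead is counted; one at 25,000 bp is not."""
        from lociforge.ld_clump import RiskLocus, SnpClassification
        import pandas as pd

        c = SnpClassification(
            significant=["lead"], independent_significant=["lead"],
            leads=["lead"], candidates={"lead": [("lead", 1.0)]},
            snp_chrom={"lead": "1"}, snp_pos={"lead": 1_000_000},
            snp_p={"lead": 1e-9})
        locus = RiskLocus("L1", "1", 1_000_000, 1_000_000, ("lead",),
                          ("lead",), ("lead",))
        pq = pd.DataFrame({
            "variant_id": ["near", "far"], "chrom": ["1", "1"],
            "pos": [1_019_999, 1_025_000], "protein": ["P1", "P2"]})
        df = pqtl_near_leads([locus], c, pq)
        assert df.loc[0, "n_pqtl"] == 1 and df.loc[0, "pqtl_variants"] == "near"


class TestDegAndSc:
    def test_null_odds_ratio_close_to_one(self):
        from lociforge.deg_integration import fisher_enrichment
        ors = []
        for rep in range(30):
            cfg = SimConfig(deg=DEGConfig(n_background_genes=3000,
                                          odds_ratio=1.0, datasets=("d1",)))
            truth = SimTruth()
            truth.planted_genes["positional"] = [f"g{i}" for i in range(300)]
            tabs = simulate_deg_tables(cfg, truth,
                                       rng=np.random.default_rng(500 + rep))
            t = tabs["d1"]
            res = fisher_enrichment(truth.all_planted_genes(),
                                    set(t.loc[t["fdr"] < 0.05, "gene_id"]),
                                    set(t["gene_id"]))
            ors.append(res.odds_ratio)
        assert abs(np.mean(ors) - 1.0) < 0.15

    def test_directions_consistent_across_datasets(self):
        cfg = small_config()
        _, truth = simulate_summary_stats(cfg)
        simulate_annotations(cfg, truth)
        tabs = simulate_deg_tables(cfg, truth)
        merged = tabs["dataset1"].merge(tabs["dataset2"], on="gene_id")
        sig_both = merged[(merged["fdr_x"] < 0.05) & (merged["fdr_y"] < 0.05)]
        assert (np.sign(sig_both["log2fc_x"]) == np.sign(sig_both["log2fc_y"])).all()

    def test_injected_violators_are_recorded_in_truth(self):
        cfg = small_config(sc=SCConfig(n_violators_per_reason=3))
        _, truth = simulate_summary_stats(cfg)
        simulate_annotations(cfg, truth)
        cm = simulate_cell_matrix(cfg, truth)
        all_violators = {v for vs in truth.violator_cells.values() for v in vs}
        assert len(all_violators) == 15
        assert all_violators <= set(cm.cell_names)

    def test_planted_modules_exist_in_matrix(self):
        cfg = small_config()
        _, truth = simulate_summary_stats(cfg)
        simulate_annotations(cfg, truth)
        cm = simulate_cell_matrix(cfg, truth)
        assert set(truth.planted_modules) <= set(cm.gene_names)
        assert set(truth.planted_modules.values()) == set(cfg.sc.cell_types)


class TestDeterminism:
    def test_write_all_is_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = small_config(sc=SCConfig(n_genes_total=2600,
                                       n_violators_per_reason=1))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_all(cfg, d1)
        write_all(cfg, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        p1 = simulate_panel(small_config(seed=1))
        p2 = simulate_panel(small_config(seed=2))
        assert not np.array_equal(p1.dosages, p2.dosages)


def test_snp_metadata_layout():
    cfg = small_config()
    meta = snp_metadata(cfg)
    assert len(meta) == 30
    assert meta["snp_id"].is_unique
    assert set(meta["chrom"]) == {"1", "2", "3"}
    assert ((meta["maf"] > 0.05) & (meta["maf"] <= 0.5)).all()
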