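import numpy as np
import pandas as pd
import pytest

from lociforge.celltype_modules import (CellMatrix, celltype_profile,
                                        cell_metadata, composition,
                                        normalize_cp10k_log1p, qc_filter_cells)


def matrix_with_cells(columns, gene_names=None):
    """Build a CellMatrix from per-cell count columns (dict name -> vector)."""
    names = list(columns)
    counts = np.column_stack([columns[c] for c in names])
    ng = counts.shape[0]
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(ng)]
    return CellMatrix(counts, gene_names, names)


def qc_fixture():
    """300 genes incl. markers; one clean cell and one violator per reason."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(282)] + \
        [f"MT-G{i}" for i in range(13)] + ["HBA1", "HBA2", "HBB", "EPCAM", "KRT18"]
    idx = {g: i for i, g in enumerate(genes)}

    def clean():
        col = rng.poisson(3.0, size=300).astype(float) + 1.0   # every gene detected
        for g in ("EPCAM", "KRT18"):
            col[idx[g]] = 0
        for g in ("HBA1", "HBA2", "HBB"):
            col[idx[g]] = 0
        for i in range(13):
            col[idx[f"MT-G{i}"]] = 1.0       # ~1% mito
        return col

    cols = {"ok": clean()}
    low = np.zeros(300); low[:150] = 1
    cols["low_feat"] = low
    mito = clean(); mito[[idx[f"MT-G{i}"] for i in range(13)]] = 20.0   # ~ 20%
    cols["mito"] = mito
    hb = clean(); hb[idx["HBB"]] = 40.0                                 # ~ 4%
    cols["hb"] = hb
    epi = clean(); epi[idx["EPCAM"]] = 1.0
    cols["epi"] = epi
    return matrix_with_cells(cols, genes)


class TestQcFilter:
    def test_each_violator_removed_for_its_reason(self):
        cm = qc_fixture()
        filtered, removed = qc_filter_cells(cm)
        assert filtered.cell_names == ["ok"]
        reasons = dict(zip(removed["cell"], removed["reasons"]))
        assert reasons["low_feat"] == "features"
        assert reasons["mito"] == "mito"
        assert reasons["hb"] == "hb"
        assert reasons["epi"] == "epithelial"

    def test_feature_bounds_inclusive(self):
        genes = [f"g{i}" for i in range(3000)]
        at200 = np.zeros(3000); at200[:200] = 1
        at199 = np.zeros(3000); at199[:199] = 1
        at2500 = np.zeros(3000); at2500[:2500] = 1
        at2501 = np.zeros(3000); at2501[:2501] = 1
        cm = matrix_with_cells({"a": at200, "b": at199, "c": at2500,
                                "d": at2501}, genes)
        filtered, removed = qc_filter_cells(cm)
        assert filtered.cell_names == ["a", "c"]

    def test_filter_is_idempotent(self):
        cm = qc_fixture()
        once, _ = qc_filter_cells(cm)
        twice, removed = qc_filter_cells(once)
        assert twice.cell_names == once.cell_names and removed.empty

    def test_missing_markers_skip_criterion_with_warning(self, caplog):
        import logging
        cm = matrix_with_cells({"a": np.ones(250)},
                               [f"g{i}" for i in range(250)])
        with caplog.at_level(logging.WARNING):
            meta = cell_metadata(cm)
        assert not meta["epithelial_detected"].iloc[0]
        assert "missing" in caplog.text


class TestComposition:
    def test_even_split(self):
        comp = composition(["SMC", "SMC", "Fib", "Fib"])
        assert comp["SMC"] == 50.0 and comp["Fib"] == 50.0

    def test_single_type_is_100(self):
        assert composition(["SMC"] * 7).iloc[0] == 100.0

    def test_three_way_counts(self):
        comp = composition(["SMC"] * 3 + ["Fib"] + ["Endo"])
        assert comp["SMC"] == 60.0 and comp["Fib"] == 20.0 and comp["Endo"] == 20.0
        assert comp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            composition([])


class TestCelltypeProfile:
    def labelled(self, counts, labels, genes=None):
        cm = matrix_with_cells(
            {f"c{i}": counts[:, i] for i in range(counts.shape[1])}, genes)
        cm.labels = list(labels)
        return cm

    def test_gene_expressed_in_one_type_gets_that_module(self):
        counts = np.array([[9, 8, 0, 0], [1, 1, 1, 1]], dtype=float)
        cm = self.labelled(counts, ["SMC", "SMC", "Fib", "Fib"])
        prof = celltype_profile(cm, ["g0", "g1"], normalize=False)
        assert prof.module["g0"] == "SMC"

    def test_constant_gene_has_no_module(self):
        counts = np.array([[2, 2, 2, 2], [0, 5, 0, 5]], dtype=float)
        cm = self.labelled(counts, ["SMC", "SMC", "Fib", "Fib"])
        prof = celltype_profile(cm, ["g0", "g1"], normalize=False)
        assert prof.module["g0"] == "none"
        assert prof.z.loc["g0"].isna().all()

    def test_two_type_z_is_plus_minus_inv_sqrt2(self):
        counts = np.array([[0, 0, 2, 2]], dtype=float)
        cm = self.labelled(counts, ["A", "A", "B", "B"])
        prof = celltype_profile(cm, ["g0"], normalize=False)
        assert prof.z.loc["g0", "A"] == pytest.approx(-1 / np.sqrt(2))
        assert prof.z.loc["g0", "B"] == pytest.approx(+1 / np.sqrt(2))

    def test_nonconstant_z_rows_standardised(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(4.0, size=(6, 30)).astype(float)
        cm = self.labelled(counts, ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        prof = celltype_profile(cm, [f"g{i}" for i in range(6)])
        z = prof.z.dropna(how="all")
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_pct_expressing_counts_raw_nonzeros(self):
        counts = np.array([[3, 0, 1, 0]], dtype=float)
        cm = self.labelled(counts, ["A", "A", "B", "B"])
        prof = celltype_profile(cm, ["g0"], normalize=False)
        assert prof.pct_expressing.loc["g0", "A"] == 0.5
        assert prof.pct_expressing.loc["g0", "B"] == 0.5

    def test_single_cell_type_is_error(self):
        counts = np.ones((2, 3))
        cm = self.labelled(counts, ["A", "A", "A"])
        with pytest.raises(ValueError, match="2 cell types"):
            celltype_profile(cm, ["g0"])

    def test_absent_candidate_genes_skipped(self, caplog):
        import logging
        counts = np.array([[1, 5], [2, 2]], dtype=float)
        cm = self.labelled(counts, ["A", "B"])
        with caplog.at_level(logging.WARNING):
            prof = celltype_profile(cm, ["g0", "missing"], normalize=False)
        assert list(prof.mean.index) == ["g0"]


def test_cp10k_normalisation_depth_invariance():
    counts = np.array([[10.0, 100.0], [30.0, 300.0]])
    norm = normalize_cp10k_log1p(counts)
    assert np.allclose(norm[:, 0], norm[:, 1])
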