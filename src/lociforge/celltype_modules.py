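"""Single-cell QC, cell-type composition and per-gene cell-type modules.

QC keeps a cell when all of the following hold: 200 ≤ detected features
≤ 2500 (inclusive bounds), mitochondrial fraction ≤ 7% of counts,
haemoglobin (HBA1/HBA2/HBB) fraction ≤ 1%, and no detectable EPCAM or
KRT18 count (epithelial/endometrioid contamination).  The filter is a
per-cell predicate — order-independent and idempotent.

Cell-type profiles: counts are normalised (counts-per-10k, log1p), the
per-gene mean is taken within each labelled cell type, and each gene row
is z-scored with the sample SD (the ``scale="row"`` convention of
pheatmap).  A gene's *module* is the cell type with the largest z
(lexicographically first on ties, flagged); a constant row has no module.
Percent-expressing is the fraction of a type's cells with a raw count > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"
HB_GENES = ("HBA1", "HBA2", "HBB")
EPITHELIAL_GENES = ("EPCAM", "KRT18")

QC_MIN_FEATURES = 200
QC_MAX_FEATURES = 2500
QC_MAX_PCT_MITO = 7.0
QC_MAX_PCT_HB = 1.0


@dataclass
class CellMatrix:
    """Raw gene × cell counts with optional cell-type labels."""

    counts: np.ndarray             # (n_genes, n_cells), non-negative
    gene_names: list[str]
    cell_names: list[str]
    labels: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene × cell matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        ng, nc = self.counts.shape
        if len(self.gene_names) != ng or len(self.cell_names) != nc:
            raise ValueError("name lengths must match the matrix shape")
        if self.labels is not None and len(self.labels) != nc:
            raise ValueError("one label per cell required")
        self._gene_index = {g: i for i, g in enumerate(self.gene_names)}

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_row(self, gene: str) -> np.ndarray:
        return self.counts[self._gene_index[gene]]

    def to_anndata(self):
        """Export as an AnnData (cells as obs, genes as var) for interop."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_names, name="cell")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        if self.labels is not None:
            adata.obs["cell_type"] = list(self.labels)
        meta = cell_metadata(self)
        for col in meta.columns:
            adata.obs[col] = meta[col].to_numpy()
        return adata


def cell_metadata(
    cm: CellMatrix,
    mito_genes: list[str] | None = None,
    hb_genes: list[str] | None = None,
    epithelial_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell QC metadata: n_features, pct_mito, pct_hb, epithelial detection.

    Marker lists default to the ``MT-`` prefix, HBA1/HBA2/HBB and
    EPCAM/KRT18; markers missing from the matrix are skipped with a warning
    (that criterion then never fires).
    """
    genes = cm.gene_names
    if mito_genes is None:
        mito_genes = [g for g in genes if g.upper().startswith(MITO_PREFIX)]
    if hb_genes is None:
        hb_genes = list(HB_GENES)
    if epithelial_genes is None:
        epithelial_genes = list(EPITHELIAL_GENES)

    def _rows(wanted, what):
        present = [g for g in wanted if g in cm._gene_index]
        missing = set(wanted) - set(present)
        if missing and wanted:
            logger.warning("%s markers missing from matrix: %s", what, sorted(missing))
        return [cm._gene_index[g] for g in present]

    totals = cm.counts.sum(axis=0)
    safe_totals = np.where(totals > 0, totals, 1.0)
    mito_rows = _rows(mito_genes, "mitochondrial")
    hb_rows = _rows(hb_genes, "haemoglobin")
    epi_rows = _rows(epithelial_genes, "epithelial")
    return pd.DataFrame({
        "n_features": (cm.counts > 0).sum(axis=0),
        "pct_mito": 100.0 * cm.counts[mito_rows].sum(axis=0) / safe_totals
        if mito_rows else np.zeros(cm.n_cells),
        "pct_hb": 100.0 * cm.counts[hb_rows].sum(axis=0) / safe_totals
        if hb_rows else np.zeros(cm.n_cells),
        "epithelial_detected": cm.counts[epi_rows].sum(axis=0) >= 1
        if epi_rows else np.zeros(cm.n_cells, dtype=bool),
    }, index=pd.Index(cm.cell_names, name="cell"))


def qc_filter_cells(
    cm: CellMatrix,
    mito_genes: list[str] | None = None,
    hb_genes: list[str] | None = None,
    epithelial_genes: list[str] | None = None,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Apply the QC predicate; returns the filtered matrix and a removal table.

    The removal table has one row per *removed* cell listing every violated
    criterion (``features``, ``mito``, ``hb``, ``epithelial``).
    """
    meta = cell_metadata(cm, mito_genes, hb_genes, epithelial_genes)
    keep = np.ones(cm.n_cells, dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(cm.n_cells)]
    feat = meta["n_features"].to_numpy()
    for i in range(cm.n_cells):
        if not (QC_MIN_FEATURES <= feat[i] <= QC_MAX_FEATURES):
            reasons[i].append("features")
        if meta["pct_mito"].iloc[i] > QC_MAX_PCT_MITO:
            reasons[i].append("mito")
        if meta["pct_hb"].iloc[i] > QC_MAX_PCT_HB:
            reasons[i].append("hb")
        if meta["epithelial_detected"].iloc[i]:
            reasons[i].append("epithelial")
        keep[i] = not reasons[i]
    removed = pd.DataFrame({
        "cell": [cm.cell_names[i] for i in range(cm.n_cells) if not keep[i]],
        "reasons": [";".join(reasons[i]) for i in range(cm.n_cells) if not keep[i]],
    })
    filtered = CellMatrix(
        counts=cm.counts[:, keep],
        gene_names=list(cm.gene_names),
        cell_names=[c for c, k in zip(cm.cell_names, keep) if k],
        labels=None if cm.labels is None
        else [l for l, k in zip(cm.labels, keep) if k],
    )
    return filtered, removed


def composition(labels) -> pd.Series:
    """Cell-type composition as percentages summing to 100."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label set")
    counts = pd.Series(labels).value_counts().sort_index()
    return 100.0 * counts / counts.sum()


def normalize_cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10k depth normalisation followed by log1p."""
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts / safe * 1e4)


@dataclass
class CellTypeProfile:
    """Gene × cell-type summary: means, row z-scores, modules, pct expressing."""

    mean: pd.DataFrame             # genes × types, normalised means
    z: pd.DataFrame                # row-standardised means (NaN rows = constant)
    module: pd.Series              # per-gene argmax type, "none" for constant rows
    pct_expressing: pd.DataFrame   # fraction of the type's cells with count > 0
    tie_flag: pd.Series = field(default=None)

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.mean.index, "module": self.module.values})
        for t in self.mean.columns:
            out[f"mean_{t}"] = self.mean[t].values
            out[f"z_{t}"] = self.z[t].values
            out[f"pct_{t}"] = self.pct_expressing[t].values
        return out


def celltype_profile(
    cm: CellMatrix,
    candidate_genes: list[str],
    normalize: bool = True,
) -> CellTypeProfile:
    """Mean/z/module/percent-expressing profile of candidate genes by cell type.

    Requires labelled cells and ≥2 cell types (z is undefined otherwise).
    Candidate genes absent from the matrix are logged and skipped.
    """
    if cm.labels is None:
        raise ValueError("cell matrix has no cell-type labels")
    types = sorted(set(cm.labels))
    if len(types) < 2:
        raise ValueError("at least 2 cell types required for row z-scores")
    present = [g for g in candidate_genes if g in cm._gene_index]
    missing = [g for g in candidate_genes if g not in cm._gene_index]
    if missing:
        logger.warning("%d candidate genes absent from the matrix: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no candidate genes present in the matrix")

    data = normalize_cp10k_log1p(cm.counts) if normalize else cm.counts
    rows = [cm._gene_index[g] for g in present]
    label_arr = np.asarray(cm.labels)
    mean = pd.DataFrame(
        {t: data[np.ix_(rows, label_arr == t)].mean(axis=1) for t in types},
        index=pd.Index(present, name="gene_id"))
    pct = pd.DataFrame(
        {t: (cm.counts[np.ix_(rows, label_arr == t)] > 0).mean(axis=1) for t in types},
        index=mean.index)

    mu = mean.mean(axis=1)
    sd = mean.std(axis=1, ddof=1)
    z = mean.sub(mu, axis=0).div(sd.where(sd > 0), axis=0)   # constant rows -> NaN

    modules, ties = [], []
    for g in present:
        row = z.loc[g]
        if row.isna().all():
            modules.append("none")
            ties.append(False)
            continue
        top = row.max()
        winners = sorted(row.index[row == top])
        modules.append(winners[0])
        ties.append(len(winners) > 1)
    tie = pd.Series(ties, index=mean.index, name="tie")
    if tie.any():
        logger.warning("%d genes had tied module z-scores; lexicographically first kept",
                       int(tie.sum()))
    return CellTypeProfile(
        mean=mean, z=z,
        module=pd.Series(modules, index=mean.index, name="module"),
        pct_expressing=pct, tie_flag=tie,
    )
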