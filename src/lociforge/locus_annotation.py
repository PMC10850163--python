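"""Per-locus annotation: nearby pQTL variants and differential signal tests.

pQTL proximity: a serum-protein pQTL variant annotates a lead SNP when it
lies within ±20 kb of it (inclusive); a locus's count is over *distinct*
pQTL variants across its leads.

Differential signal: per-locus H3K27ac intensity or Hi-C contact strength
is aggregated as the unweighted mean over the locus's member genes (or
contacts) per sample, then compared between the disease and control
groups with a pooled-variance two-sided Student t test (df = n1 + n2 − 2).
Welch's correction is available as a switch but the pooled test is the
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld_clump import RiskLocus, SnpClassification, Thresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PQTLRecord:
    variant_id: str
    chrom: str
    pos: int
    protein: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")


@dataclass
class LocusSignalScores:
    """Per-sample aggregated signal for one locus, with group labels."""

    locus_id: str
    scores: np.ndarray
    groups: list[str]       # e.g. "tumor" / "control" per sample

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError(f"{self.locus_id}: non-finite signal score")
        if len(self.groups) != len(self.scores):
            raise ValueError("group labels and scores differ in length")


# ---------------------------------------------------------------------------
# pQTL proximity
# ---------------------------------------------------------------------------

def pqtl_near_leads(
    loci: list[RiskLocus],
    classification: SnpClassification,
    pqtl_records,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Count pQTL variants within ±``pqtl_window_bp`` of each lead SNP.

    Returns one row per locus with the distinct pQTL variant count and the
    protein names; per-lead hits are in the ``per_lead`` column
    (lead=var1|var2 entries joined by ';').
    """
    records = _as_pqtl_records(pqtl_records)
    rows = []
    for locus in loci:
        per_lead = {}
        hits: dict[str, str] = {}
        for lead in locus.lead_snp_ids:
            lc, lp = classification.snp_chrom[lead], classification.snp_pos[lead]
            near = [r for r in records
                    if r.chrom == lc and abs(r.pos - lp) <= thresholds.pqtl_window_bp]
            per_lead[lead] = [r.variant_id for r in near]
            for r in near:
                hits[r.variant_id] = r.protein
        rows.append({
            "locus_id": locus.locus_id,
            "n_pqtl": len(hits),
            "pqtl_variants": ";".join(sorted(hits)),
            "pqtl_proteins": ";".join(sorted(set(hits.values()))),
            "per_lead": ";".join(f"{l}={'|'.join(v)}" for l, v in per_lead.items()),
        })
    return pd.DataFrame(rows)


def _as_pqtl_records(records) -> list[PQTLRecord]:
    if isinstance(records, pd.DataFrame):
        return [PQTLRecord(str(r.variant_id), str(r.chrom), int(r.pos), str(r.protein))
                for r in records.itertuples()]
    return list(records)


# ---------------------------------------------------------------------------
# per-locus signal aggregation and testing
# ---------------------------------------------------------------------------

def locus_signal(
    gene_sample_matrix: pd.DataFrame,
    locus_genes: dict[str, list[str]],
    groups: list[str],
) -> list[LocusSignalScores]:
    """Aggregate a gene × sample signal table to per-locus per-sample means.

    ``gene_sample_matrix`` rows are genes (or contacts), columns samples;
    ``locus_genes`` maps locus_id to its member gene ids.  A locus with no
    member present in the table is skipped with a warning.
    """
    if len(groups) != gene_sample_matrix.shape[1]:
        raise ValueError("one group label required per sample column")
    out = []
    for locus_id, genes in locus_genes.items():
        present = [g for g in genes if g in gene_sample_matrix.index]
        if not present:
            logger.warning("locus %s has no member genes in the signal table; skipped",
                           locus_id)
            continue
        scores = gene_sample_matrix.loc[present].mean(axis=0).to_numpy()
        out.append(LocusSignalScores(locus_id, scores, list(groups)))
    return out


def differential_t_test(scores: LocusSignalScores, welch: bool = False
                        ) -> tuple[float, float, dict[str, float]]:
    """Two-sided Student t test between the two sample groups of one locus.

    Returns ``(t, p, group_means)``.  Pooled-variance by default
    (df = n1+n2−2); zero pooled variance with equal means gives t=0, P=1.
    Fewer than 2 samples in a group is an error naming that group.
    """
    labels = sorted(set(scores.groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    g1 = scores.scores[[g == labels[0] for g in scores.groups]]
    g2 = scores.scores[[g == labels[1] for g in scores.groups]]
    for name, g in zip(labels, (g1, g2)):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    t, p = sps.ttest_ind(g1, g2, equal_var=not welch)
    if np.isnan(t):   # zero variance in both groups
        t, p = (0.0, 1.0) if np.isclose(g1.mean(), g2.mean()) else (np.inf, 0.0)
    means = {labels[0]: float(g1.mean()), labels[1]: float(g2.mean())}
    return float(t), float(p), means


def annotate_loci(
    loci: list[RiskLocus],
    classification: SnpClassification,
    pqtl_records=None,
    signal_tables: dict[str, pd.DataFrame] | None = None,
    locus_genes: dict[str, list[str]] | None = None,
    groups: list[str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One annotation row per locus: pQTL counts plus per-signal t/P columns."""
    if pqtl_records is not None:
        df = pqtl_near_leads(loci, classification, pqtl_records, thresholds)
    else:
        df = pd.DataFrame({"locus_id": [l.locus_id for l in loci]})
    if signal_tables and locus_genes is not None and groups is not None:
        for name, table in signal_tables.items():
            stats_by_locus = {}
            for s in locus_signal(table, locus_genes, groups):
                t, p, means = differential_t_test(s)
                stats_by_locus[s.locus_id] = (t, p)
            df[f"{name}_t"] = [stats_by_locus.get(l, (np.nan, np.nan))[0]
                               for l in df["locus_id"]]
            df[f"{name}_p"] = [stats_by_locus.get(l, (np.nan, np.nan))[1]
                               for l in df["locus_id"]]
    return df
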