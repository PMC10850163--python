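"""LD-based clumping of GWAS summary statistics into genomic risk loci.

The classification follows the standard three-tier scheme used by GWAS
post-processing tools:

* **independent significant SNPs** — genome-wide significant SNPs
  (P < 5e-8) that are mutually independent at r² < 0.8, selected greedily
  in order of ascending P;
* **lead SNPs** — the subset of independent significant SNPs that are
  mutually independent at the stricter r² < 0.1;
* **candidate SNPs** — every GWAS SNP (at any P) in LD (r² > 0.8) with at
  least one independent significant SNP, including that SNP itself.

LD blocks (the positional span of each independent significant SNP's
candidates) are then merged into **genomic risk loci**: two blocks on the
same chromosome join the same locus when their independent significant
SNPs are correlated at r² ≥ 0.1 or the blocks lie closer than 250 kb;
loci are the connected components of that graph.

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD) from the reference panel, with missing dosages mean-imputed
per SNP.  Significant GWAS SNPs absent from the panel are kept as
independent-significant singletons (r² treated as 0 to everything) with a
logged count, rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import GenotypePanel, SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cutoff of the pipeline, defaulting to the study values."""

    p_gw: float = 5e-8            # genome-wide significance
    r2_indep: float = 0.8         # independence cutoff
    r2_lead: float = 0.1          # lead-SNP cutoff
    merge_gap_bp: int = 250_000   # LD-block merge distance
    pos_window_bp: int = 10_000   # positional gene-mapping window
    eqtl_fdr: float = 0.05
    hic_fdr: float = 1e-6
    promoter_up_bp: int = 250     # upstream of TSS
    promoter_down_bp: int = 500   # downstream of TSS
    pqtl_window_bp: int = 20_000  # ±window around each lead SNP
    deg_fdr: float = 0.05

    def __post_init__(self):
        for name in ("p_gw", "r2_indep", "r2_lead", "merge_gap_bp", "pos_window_bp",
                     "eqtl_fdr", "hic_fdr", "promoter_up_bp", "promoter_down_bp",
                     "pqtl_window_bp", "deg_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if not (self.r2_lead < self.r2_indep <= 1):
            raise ValueError("require r2_lead < r2_indep <= 1")


@dataclass
class SnpClassification:
    """Per-SNP tier flags plus candidate-tagging structure.

    ``candidates`` maps each candidate SNP id to the list of
    ``(independent_significant_id, tagging_r2)`` pairs tagging it.
    ``indep_r2`` is the pairwise r² matrix over independent significant
    SNPs, in ``independent_significant`` order.
    """

    significant: list[str]
    independent_significant: list[str]
    leads: list[str]
    candidates: dict[str, list[tuple[str, float]]]
    snp_chrom: dict[str, str]
    snp_pos: dict[str, int]
    snp_p: dict[str, float]
    indep_r2: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    absent_from_panel: list[str] = field(default_factory=list)

    def is_significant(self, snp_id: str) -> bool:
        return snp_id in self._sig_set

    def is_independent_significant(self, snp_id: str) -> bool:
        return snp_id in self._indep_set

    def is_lead(self, snp_id: str) -> bool:
        return snp_id in self._lead_set

    def is_candidate(self, snp_id: str) -> bool:
        return snp_id in self.candidates

    def __post_init__(self):
        self._sig_set = set(self.significant)
        self._indep_set = set(self.independent_significant)
        self._lead_set = set(self.leads)

    def tagged_by(self, indep_snp: str) -> list[str]:
        """Candidate SNP ids tagged by one independent significant SNP."""
        return [c for c, tags in self.candidates.items()
                if any(i == indep_snp for i, _ in tags)]


@dataclass(frozen=True)
class RiskLocus:
    """A merged genomic risk locus spanning its member candidate SNPs."""

    locus_id: str
    chrom: str
    start: int
    end: int
    lead_snp_ids: tuple[str, ...]
    independent_significant_ids: tuple[str, ...]
    candidate_ids: tuple[str, ...]

    @property
    def n_independent_significant(self) -> int:
        return len(self.independent_significant_ids)

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ids)


# ---------------------------------------------------------------------------
# r² computation
# ---------------------------------------------------------------------------

def compute_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD).

    Missing dosages are mean-imputed per SNP.  A monomorphic SNP is
    defined unlinkable: r² = 0 with a warning.  An absent SNP is an error.
    """
    ia, ib = panel.index(snp_a), panel.index(snp_b)
    x = panel.imputed_dosages([ia, ib])
    return _r2_cols(x[:, 0], x[:, 1])


def _r2_cols(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        logger.warning("monomorphic SNP in r2 computation; treating as unlinkable (r2=0)")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def _r2_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise r² between the columns of ``x`` (n×p) and ``y`` (n×q)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    num = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / np.outer(sx, sy)
    r = np.where(np.isfinite(r), r, 0.0)   # monomorphic -> unlinkable
    return np.clip(r * r, 0.0, 1.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _greedy_order(records: list[SummaryStatRecord]) -> list[SummaryStatRecord]:
    # ascending P; ties broken by ascending position then lexicographic id
    return sorted(records, key=lambda r: (r.p, r.pos, r.snp_id))


def classify_snps(
    stats: list[SummaryStatRecord],
    panel: GenotypePanel,
    thresholds: Thresholds = Thresholds(),
) -> SnpClassification:
    """Three-tier greedy classification of GWAS SNPs against the LD panel."""
    snp_chrom = {r.snp_id: r.chrom for r in stats}
    snp_pos = {r.snp_id: r.pos for r in stats}
    snp_p = {r.snp_id: r.p for r in stats}

    significant = [r for r in stats if r.p < thresholds.p_gw]
    sig_ids = [r.snp_id for r in _greedy_order(significant)]

    absent = [s for s in sig_ids if s not in panel]
    if absent:
        logger.warning(
            "%d significant SNPs absent from the reference panel; "
            "kept as independent-significant singletons", len(absent))

    in_panel_cols = {s: panel.index(s) for s in sig_ids if s in panel}
    imput = panel.imputed_dosages()

    # greedy independence walk at r2_indep
    indep: list[str] = []
    for s in sig_ids:
        if s not in in_panel_cols:
            indep.append(s)           # unlinkable singleton
            continue
        col = imput[:, in_panel_cols[s]]
        accept = True
        for t in indep:
            if t not in in_panel_cols or snp_chrom[t] != snp_chrom[s]:
                continue  # inter-chromosomal r2 is never computed
            if _r2_cols(col, imput[:, in_panel_cols[t]]) >= thresholds.r2_indep:
                accept = False
                break
        if accept:
            indep.append(s)

    # greedy lead walk at r2_lead over the independent significant SNPs
    leads: list[str] = []
    for s in indep:   # already in (p, pos, id) order
        if s not in in_panel_cols:
            leads.append(s)
            continue
        col = imput[:, in_panel_cols[s]]
        accept = True
        for t in leads:
            if t not in in_panel_cols or snp_chrom[t] != snp_chrom[s]:
                continue
            if _r2_cols(col, imput[:, in_panel_cols[t]]) >= thresholds.r2_lead:
                accept = False
                break
        if accept:
            leads.append(s)

    # candidates: every GWAS SNP with r2 > r2_indep to >=1 independent
    # significant SNP (an indep SNP tags itself at r2 = 1)
    candidates: dict[str, list[tuple[str, float]]] = {}
    gwas_in_panel = [r.snp_id for r in stats if r.snp_id in panel]
    if indep and gwas_in_panel:
        indep_in_panel = [s for s in indep if s in in_panel_cols]
        if indep_in_panel:
            icols = [in_panel_cols[s] for s in indep_in_panel]
            gcols = [panel.index(s) for s in gwas_in_panel]
            # chromosome gate: r2 only meaningful within a chromosome
            r2 = _r2_matrix(imput[:, icols], imput[:, gcols])
            for j, g in enumerate(gwas_in_panel):
                tags = [
                    (indep_in_panel[i], float(r2[i, j]))
                    for i in range(len(indep_in_panel))
                    if snp_chrom[indep_in_panel[i]] == snp_chrom[g]
                    and r2[i, j] > thresholds.r2_indep
                ]
                if tags:
                    candidates[g] = tags
    for s in indep:      # every indep SNP tags itself (r2 = 1); covers panel-absent singletons
        tags = candidates.setdefault(s, [])
        if not any(i == s for i, _ in tags):
            tags.append((s, 1.0))

    # pairwise r2 among independent significant SNPs, for locus merging
    k = len(indep)
    indep_r2 = np.zeros((k, k))
    for i in range(k):
        indep_r2[i, i] = 1.0
        for j in range(i + 1, k):
            a, b = indep[i], indep[j]
            if a in in_panel_cols and b in in_panel_cols and snp_chrom[a] == snp_chrom[b]:
                v = _r2_cols(imput[:, in_panel_cols[a]], imput[:, in_panel_cols[b]])
            else:
                v = 0.0
            indep_r2[i, j] = indep_r2[j, i] = v

    return SnpClassification(
        significant=[r.snp_id for r in significant],
        independent_significant=indep,
        leads=leads,
        candidates=candidates,
        snp_chrom=snp_chrom,
        snp_pos=snp_pos,
        snp_p=snp_p,
        indep_r2=indep_r2,
        absent_from_panel=absent,
    )


def ld_block(classification: SnpClassification, indep_snp: str) -> tuple[str, int, int]:
    """Positional span (chrom, min pos, max pos) of one clump's candidates."""
    if not classification.is_independent_significant(indep_snp):
        raise ValueError(f"{indep_snp!r} is not an independent significant SNP")
    tagged = classification.tagged_by(indep_snp)
    chrom = classification.snp_chrom[indep_snp]
    positions = [classification.snp_pos[s] for s in tagged
                 if classification.snp_chrom[s] == chrom]
    positions.append(classification.snp_pos[indep_snp])
    return chrom, min(positions), max(positions)


def define_risk_loci(
    classification: SnpClassification,
    thresholds: Thresholds = Thresholds(),
) -> list[RiskLocus]:
    """Merge LD blocks into risk loci by transitive closure.

    Two independent significant SNPs on the same chromosome are connected
    when their r² ≥ ``r2_lead`` or the gap between their LD blocks is
    smaller than ``merge_gap_bp``; loci are the connected components,
    each spanning the union of its member blocks.
    """
    indep = classification.independent_significant
    if not indep:
        return []
    blocks = {s: ld_block(classification, s) for s in indep}

    g = nx.Graph()
    g.add_nodes_from(indep)
    for i in range(len(indep)):
        ci, si, ei = blocks[indep[i]]
        for j in range(i + 1, len(indep)):
            cj, sj, ej = blocks[indep[j]]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej)  # <=0 when blocks touch/overlap
            if classification.indep_r2[i, j] >= thresholds.r2_lead or gap < thresholds.merge_gap_bp:
                g.add_edge(indep[i], indep[j])

    loci = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        chrom = blocks[members[0]][0]
        start = min(blocks[m][1] for m in members)
        end = max(blocks[m][2] for m in members)
        cands = sorted({c for m in members for c in classification.tagged_by(m)} | set(members))
        leads = tuple(s for s in classification.leads if s in comp)
        loci.append((chrom, start, end, leads, tuple(members), tuple(cands)))

    loci.sort(key=lambda t: (_chrom_key(t[0]), t[1], t[2]))
    return [
        RiskLocus(
            locus_id=f"locus_{i + 1}", chrom=c, start=s, end=e,
            lead_snp_ids=leads, independent_significant_ids=members,
            candidate_ids=cands,
        )
        for i, (c, s, e, leads, members, cands) in enumerate(loci)
    ]


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def classification_frame(classification: SnpClassification):
    """Per-SNP classification as a tidy DataFrame (for the TSV export)."""
    import pandas as pd

    rows = []
    ids = sorted(set(classification.snp_p)
                 | set(classification.candidates), key=lambda s: (
        _chrom_key(classification.snp_chrom.get(s, "")),
        classification.snp_pos.get(s, 0), s))
    for s in ids:
        tags = classification.candidates.get(s, [])
        rows.append({
            "snp_id": s,
            "chrom": classification.snp_chrom.get(s, ""),
            "pos": classification.snp_pos.get(s, -1),
            "p": classification.snp_p.get(s, np.nan),
            "is_significant": classification.is_significant(s),
            "is_independent_significant": classification.is_independent_significant(s),
            "is_lead": classification.is_lead(s),
            "is_candidate": classification.is_candidate(s),
            "tagging_snps": ";".join(i for i, _ in tags),
            "tagging_r2": ";".join(f"{r:.4f}" for _, r in tags),
        })
    return pd.DataFrame(rows)


def locus_frame(loci: list[RiskLocus]):
    import pandas as pd

    return pd.DataFrame([{
        "locus_id": l.locus_id, "chrom": l.chrom, "start": l.start, "end": l.end,
        "n_candidates": l.n_candidates,
        "n_indep": l.n_independent_significant,
        "lead_snps": ";".join(l.lead_snp_ids),
    } for l in loci])
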