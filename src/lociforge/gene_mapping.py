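"""SNP-to-gene mapping by position, eQTL evidence and 3D chromatin contact.

A candidate SNP implicates a gene through up to three evidence channels:

* ``positional`` — the gene body lies within 10 kb of the SNP (distance 0
  inside the body, inclusive at the window);
* ``eqtl`` — an eQTL record joins the SNP to the gene at FDR < 0.05
  (strict);
* ``chromatin`` — a significant chromatin interaction (FDR < 1e-6) has one
  anchor containing the SNP inside an enhancer interval and the other
  anchor overlapping the gene's promoter window (−250/+500 bp of the TSS,
  strand-aware); anchors are unordered, both orientations are tested.

:func:`combine_evidence` takes the per-channel fragments to a per-gene
evidence union plus the counts of the seven non-empty channel subsets
(the Venn partition over {positional, eqtl, chromatin}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, IntervalRecord
from .ld_clump import RiskLocus, SnpClassification, Thresholds

logger = logging.getLogger(__name__)

CHANNELS = ("positional", "eqtl", "chromatin")


@dataclass(frozen=True)
class EQTLRecord:
    snp_id: str
    gene_id: str
    fdr: float
    tissue: str = "unspecified"

    def __post_init__(self):
        if not (0 <= self.fdr <= 1):
            raise ValueError(f"eQTL FDR must be in [0,1], got {self.fdr}")


@dataclass(frozen=True)
class InteractionRecord:
    anchor_a: IntervalRecord
    anchor_b: IntervalRecord
    fdr: float

    def __post_init__(self):
        if not (0 <= self.fdr <= 1):
            raise ValueError(f"interaction FDR must be in [0,1], got {self.fdr}")


@dataclass
class MappedGene:
    """A gene with its accumulated evidence channels and supporting SNPs."""

    gene_id: str
    evidence: set[str] = field(default_factory=set)
    source_locus_ids: set[str] = field(default_factory=set)
    snps_by_channel: dict[str, set[str]] = field(default_factory=dict)

    def add(self, channel: str, snp_ids, locus_ids):
        if channel not in CHANNELS:
            raise ValueError(f"unknown evidence channel {channel!r}")
        self.evidence.add(channel)
        self.snps_by_channel.setdefault(channel, set()).update(snp_ids)
        self.source_locus_ids.update(locus_ids)


@dataclass
class CandidateSet:
    """Candidate SNPs with positions and the loci they belong to."""

    snp_ids: list[str]
    chroms: dict[str, str]
    positions: dict[str, int]
    loci_of: dict[str, set[str]]

    @classmethod
    def from_classification(cls, classification: SnpClassification,
                            loci: list[RiskLocus]) -> "CandidateSet":
        loci_of: dict[str, set[str]] = {}
        for locus in loci:
            for s in locus.candidate_ids:
                loci_of.setdefault(s, set()).add(locus.locus_id)
        ids = sorted(classification.candidates)
        return cls(
            snp_ids=ids,
            chroms={s: classification.snp_chrom[s] for s in ids},
            positions={s: classification.snp_pos[s] for s in ids},
            loci_of={s: loci_of.get(s, set()) for s in ids},
        )


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

def snp_gene_distance(pos: int, gene: GeneModel) -> int:
    """bp distance from a SNP to the gene body; 0 inside [start, end]."""
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0


def positional_map(
    candidates: CandidateSet,
    genes: list[GeneModel],
    thresholds: Thresholds = Thresholds(),
) -> list[MappedGene]:
    """Genes whose body lies within ``pos_window_bp`` of a candidate SNP (inclusive)."""
    out: dict[str, MappedGene] = {}
    for gene in genes:
        for s in candidates.snp_ids:
            if candidates.chroms[s] != gene.chrom:
                continue
            if snp_gene_distance(candidates.positions[s], gene) <= thresholds.pos_window_bp:
                mg = out.setdefault(gene.gene_id, MappedGene(gene.gene_id))
                mg.add("positional", [s], candidates.loci_of[s])
    return list(out.values())


def eqtl_map(
    candidates: CandidateSet,
    eqtl_records,
    thresholds: Thresholds = Thresholds(),
) -> list[MappedGene]:
    """Genes joined to a candidate SNP by an eQTL record at FDR < ``eqtl_fdr``."""
    records = _as_eqtl_records(eqtl_records)
    cand = set(candidates.snp_ids)
    out: dict[str, MappedGene] = {}
    for rec in records:
        if rec.snp_id in cand and rec.fdr < thresholds.eqtl_fdr:
            mg = out.setdefault(rec.gene_id, MappedGene(rec.gene_id))
            mg.add("eqtl", [rec.snp_id], candidates.loci_of[rec.snp_id])
    return list(out.values())


def _as_eqtl_records(records) -> list[EQTLRecord]:
    if isinstance(records, pd.DataFrame):
        return [EQTLRecord(str(r.snp_id), str(r.gene_id), float(r.fdr),
                           str(getattr(r, "tissue", "unspecified")))
                for r in records.itertuples()]
    return list(records)


def promoter_window(gene: GeneModel, thresholds: Thresholds = Thresholds()) -> IntervalRecord:
    """Strand-aware promoter interval around the TSS, clipped at position 1.

    On the + strand: [tss − promoter_up_bp, tss + promoter_down_bp];
    on the − strand the window is reflected.
    """
    if gene.strand == "+":
        start, end = gene.tss - thresholds.promoter_up_bp, gene.tss + thresholds.promoter_down_bp
    else:
        start, end = gene.tss - thresholds.promoter_down_bp, gene.tss + thresholds.promoter_up_bp
    return IntervalRecord(gene.chrom, max(start, 1), end)


def chromatin_map(
    candidates: CandidateSet,
    interactions,
    enhancers: list[IntervalRecord],
    genes: list[GeneModel],
    thresholds: Thresholds = Thresholds(),
) -> list[MappedGene]:
    """Genes linked by a significant interaction from an enhancer-resident SNP.

    A gene is mapped when an interaction at FDR < ``hic_fdr`` has one anchor
    containing a candidate SNP that lies inside an enhancer interval, and the
    other anchor overlaps the gene's promoter window.  Both anchor
    orientations are tested.
    """
    records = _as_interaction_records(interactions)
    promoters = {g.gene_id: promoter_window(g, thresholds) for g in genes}

    # candidate SNPs inside at least one enhancer
    in_enh: list[str] = [
        s for s in candidates.snp_ids
        if any(e.chrom == candidates.chroms[s] and e.contains(candidates.positions[s])
               for e in enhancers)
    ]

    out: dict[str, MappedGene] = {}
    for rec in records:
        if rec.fdr >= thresholds.hic_fdr:
            continue
        for snp_side, gene_side in ((rec.anchor_a, rec.anchor_b),
                                    (rec.anchor_b, rec.anchor_a)):
            snps = [s for s in in_enh
                    if snp_side.chrom == candidates.chroms[s]
                    and snp_side.contains(candidates.positions[s])]
            if not snps:
                continue
            for gid, prom in promoters.items():
                if gene_side.overlaps(prom):
                    mg = out.setdefault(gid, MappedGene(gid))
                    for s in snps:
                        mg.add("chromatin", [s], candidates.loci_of[s])
    return list(out.values())


def _as_interaction_records(records) -> list[InteractionRecord]:
    if isinstance(records, pd.DataFrame):
        return [InteractionRecord(
            IntervalRecord(str(r.chromA), int(r.startA), int(r.endA)),
            IntervalRecord(str(r.chromB), int(r.startB), int(r.endB)),
            float(r.fdr)) for r in records.itertuples()]
    return list(records)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine_evidence(*fragment_lists: list[MappedGene]) -> tuple[list[MappedGene], dict[frozenset, int]]:
    """Union per-channel fragments into one MappedGene per gene + Venn counts.

    Returns the combined genes (sorted by id) and the counts of the seven
    non-empty subsets of {positional, eqtl, chromatin}; the cell counts sum
    to the number of distinct mapped genes.
    """
    combined: dict[str, MappedGene] = {}
    for frags in fragment_lists:
        for frag in frags:
            mg = combined.setdefault(frag.gene_id, MappedGene(frag.gene_id))
            for channel in frag.evidence:
                mg.add(channel, frag.snps_by_channel.get(channel, ()),
                       frag.source_locus_ids)
    venn = {frozenset(sub): 0 for sub in _nonempty_subsets(CHANNELS)}
    for mg in combined.values():
        venn[frozenset(mg.evidence)] += 1
    return [combined[g] for g in sorted(combined)], venn


def _nonempty_subsets(items):
    items = list(items)
    for mask in range(1, 1 << len(items)):
        yield tuple(items[i] for i in range(len(items)) if mask >> i & 1)


def gene_map_frame(mapped: list[MappedGene]) -> pd.DataFrame:
    rows = []
    for mg in mapped:
        row = {"gene_id": mg.gene_id,
               "loci": ";".join(sorted(mg.source_locus_ids))}
        for ch in CHANNELS:
            row[ch] = ch in mg.evidence
            row[f"n_snps_{ch}"] = len(mg.snps_by_channel.get(ch, ()))
        rows.append(row)
    return pd.DataFrame(rows)


def venn_frame(venn: dict[frozenset, int]) -> pd.DataFrame:
    rows = [{"channels": "&".join(ch for ch in CHANNELS if ch in key), "n_genes": n}
            for key, n in sorted(venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))]
    return pd.DataFrame(rows)
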