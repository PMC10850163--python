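"""End-to-end orchestration: clump → map-genes → annotate → degs → celltype.

Stages run in order on a :class:`PipelineInputs` bundle; a stage whose
inputs are absent is skipped.  The run produces a :class:`RunManifest`
holding the per-stage counts (with the internal consistency guarantees
leads ≤ independent-significant ≤ candidates and Venn cells summing to the
mapped-gene total) plus all stage outputs, and can write every table and
the manifest JSON to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .celltype_modules import (CellMatrix, celltype_profile, composition,
                               qc_filter_cells)
from .deg_integration import (classify_direction, enrichment_by_dataset,
                              enrichment_frame)
from .gene_mapping import (CandidateSet, chromatin_map, combine_evidence,
                           eqtl_map, gene_map_frame, positional_map, venn_frame)
from .ld_clump import (Thresholds, classification_frame, classify_snps,
                       define_risk_loci, locus_frame)
from .locus_annotation import annotate_loci

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """Everything the pipeline can consume; optional entries skip their stage."""

    stats: list = None
    panel: Any = None
    genes: list = None
    eqtl: pd.DataFrame = None
    enhancers: list = None
    interactions: pd.DataFrame = None
    pqtl: pd.DataFrame = None
    deg_tables: dict = None
    cell_matrix: CellMatrix = None
    candidate_gene_list: list = None     # genes profiled in the single-cell stage
    signal_tables: dict = None
    signal_groups: list = None


@dataclass
class RunManifest:
    """Per-stage row counts plus the configuration snapshot."""

    version: str = __version__
    thresholds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    n_gwas_snps: int = 0
    n_significant: int = 0
    n_independent_significant: int = 0
    n_leads: int = 0
    n_candidates: int = 0
    n_loci: int = 0
    n_mapped_genes: int = 0
    n_mapped_by_channel: dict = field(default_factory=dict)
    venn_counts: dict = field(default_factory=dict)
    n_pqtl_total: int = 0
    n_deg_overlap: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    n_cells_before_qc: int = 0
    n_cells_after_qc: int = 0

    def validate(self) -> None:
        if not (self.n_leads <= self.n_independent_significant <= self.n_candidates
                or self.n_candidates == 0):
            raise AssertionError("manifest count inequality violated")
        if self.venn_counts and sum(self.venn_counts.values()) != self.n_mapped_genes:
            raise AssertionError("Venn cells do not sum to the mapped-gene total")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


@dataclass
class PipelineResult:
    manifest: RunManifest
    classification: Any = None
    loci: list = None
    candidates: CandidateSet = None
    mapped_genes: list = None
    venn: dict = None
    locus_annotation: pd.DataFrame = None
    direction: pd.DataFrame = None
    enrichment: dict = None
    sc_removed: pd.DataFrame = None
    sc_composition: pd.Series = None
    sc_profile: Any = None


def run_full_pipeline(
    inputs: PipelineInputs,
    thresholds: Thresholds = Thresholds(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage whose inputs are present; optionally write all outputs."""
    manifest = RunManifest(thresholds=thresholds.__dict__.copy())
    result = PipelineResult(manifest=manifest)

    if inputs.stats is None or inputs.panel is None:
        raise ValueError("clump stage requires summary statistics and a panel")
    try:
        classification = classify_snps(inputs.stats, inputs.panel, thresholds)
        loci = define_risk_loci(classification, thresholds)
    except Exception as exc:
        raise RuntimeError(f"stage clump failed: {exc}") from exc
    result.classification, result.loci = classification, loci
    manifest.n_gwas_snps = len(inputs.stats)
    manifest.n_significant = len(classification.significant)
    manifest.n_independent_significant = len(classification.independent_significant)
    manifest.n_leads = len(classification.leads)
    manifest.n_candidates = len(classification.candidates)
    manifest.n_loci = len(loci)

    mapped = []
    if inputs.genes is not None:
        try:
            candidates = CandidateSet.from_classification(classification, loci)
            result.candidates = candidates
            fragments = [positional_map(candidates, inputs.genes, thresholds)]
            if inputs.eqtl is not None:
                fragments.append(eqtl_map(candidates, inputs.eqtl, thresholds))
            if inputs.interactions is not None and inputs.enhancers is not None:
                fragments.append(chromatin_map(candidates, inputs.interactions,
                                               inputs.enhancers, inputs.genes,
                                               thresholds))
            mapped, venn = combine_evidence(*fragments)
        except Exception as exc:
            raise RuntimeError(f"stage map-genes failed: {exc}") from exc
        result.mapped_genes, result.venn = mapped, venn
        manifest.n_mapped_genes = len(mapped)
        for ch in ("positional", "eqtl", "chromatin"):
            manifest.n_mapped_by_channel[ch] = sum(ch in m.evidence for m in mapped)
        manifest.venn_counts = {"&".join(sorted(k)): v for k, v in venn.items()}

    if inputs.pqtl is not None or inputs.signal_tables is not None:
        try:
            locus_genes = None
            if mapped:
                locus_genes = {l.locus_id: sorted(
                    m.gene_id for m in mapped if l.locus_id in m.source_locus_ids)
                    for l in loci}
            ann = annotate_loci(
                loci, classification, pqtl_records=inputs.pqtl,
                signal_tables=inputs.signal_tables, locus_genes=locus_genes,
                groups=inputs.signal_groups, thresholds=thresholds)
        except Exception as exc:
            raise RuntimeError(f"stage annotate failed: {exc}") from exc
        result.locus_annotation = ann
        if "n_pqtl" in ann.columns:
            manifest.n_pqtl_total = int(ann["n_pqtl"].sum())

    if inputs.deg_tables is not None and mapped:
        try:
            mapped_ids = [m.gene_id for m in mapped]
            result.direction = classify_direction(mapped_ids, inputs.deg_tables,
                                                  thresholds)
            result.enrichment = enrichment_by_dataset(mapped_ids, inputs.deg_tables,
                                                      thresholds)
        except Exception as exc:
            raise RuntimeError(f"stage degs failed: {exc}") from exc
        for name, res in result.enrichment.items():
            manifest.n_deg_overlap[name] = res.a
            manifest.enrichment[name] = {
                "odds_ratio": res.odds_ratio, "p_two_sided": res.p_two_sided}

    if inputs.cell_matrix is not None:
        try:
            manifest.n_cells_before_qc = inputs.cell_matrix.n_cells
            filtered, removed = qc_filter_cells(inputs.cell_matrix)
            manifest.n_cells_after_qc = filtered.n_cells
            result.sc_removed = removed
            result.sc_composition = composition(filtered.labels)
            genes_to_profile = (inputs.candidate_gene_list
                                or [m.gene_id for m in mapped]) or None
            if genes_to_profile:
                present = [g for g in genes_to_profile
                           if g in filtered._gene_index]
                if present:
                    result.sc_profile = celltype_profile(filtered, present)
        except Exception as exc:
            raise RuntimeError(f"stage celltype failed: {exc}") from exc

    manifest.validate()
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    classification_frame(result.classification).to_csv(
        outdir / "snp_classification.tsv", sep="\t", index=False)
    locus_frame(result.loci).to_csv(outdir / "risk_loci.tsv", sep="\t", index=False)
    if result.mapped_genes is not None:
        gene_map_frame(result.mapped_genes).to_csv(
            outdir / "gene_map.tsv", sep="\t", index=False)
        venn_frame(result.venn).to_csv(outdir / "venn_counts.tsv", sep="\t",
                                       index=False)
    if result.locus_annotation is not None:
        result.locus_annotation.to_csv(outdir / "locus_annotation.tsv", sep="\t",
                                       index=False)
    if result.direction is not None:
        result.direction.to_csv(outdir / "deg_direction.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        enrichment_frame(result.enrichment).to_csv(outdir / "enrichment.tsv",
                                                   sep="\t", index=False)
    if result.sc_composition is not None:
        result.sc_composition.rename("percent").to_csv(
            outdir / "celltype_composition.tsv", sep="\t")
    if result.sc_profile is not None:
        result.sc_profile.frame().to_csv(outdir / "celltype_profile.tsv",
                                         sep="\t", index=False)
    if result.sc_removed is not None:
        result.sc_removed.to_csv(outdir / "qc_removed_cells.tsv", sep="\t",
                                 index=False)
    result.manifest.to_json(outdir / "manifest.json")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
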