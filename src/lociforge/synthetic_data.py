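"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of the real inputs:

* **reference panel** — block-structured LD from a first-order copying
  chain: within a block, SNP k+1 copies SNP k's haplotype allele with
  probability ρ, else redraws from its MAF; diploid dosage is the sum of
  two independent haplotypes.  Adjacent-SNP haplotype r² is ≈ ρ² in
  expectation, so LD decay is directly tunable; blocks are independent.
* **summary statistics** — a quantitative phenotype y = Σ β·g + N(0,1)
  over a freshly simulated cohort (not the panel itself, so panel r² and
  association are realistically decoupled), with per-SNP P values from
  marginal simple regression.
* **annotations** — gene models, eQTL, enhancer, interaction and pQTL
  tables in which the planted channels are guaranteed hits and decoys are
  guaranteed misses by construction.
* **DEG tables** — DE membership sampled so the planted-gene/DE-gene odds
  ratio equals a configured value; directions consistent across datasets.
* **single-cell counts** — negative-binomial counts with cell-type-specific
  gene modules (mean × fold in the home type) and deterministically
  constructed QC-violating cells appended.

All randomness flows from one seed via ``numpy.random.SeedSequence``
spawning, so a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .celltype_modules import CellMatrix
from .io_formats import (
    GeneModel, GenotypePanel, IntervalRecord, SummaryStatRecord,
    write_dosage_panel, write_expression_matrix, write_gene_models,
    write_intervals, write_summary_stats, BED_0HALF,
)

_CAUSAL_ALLELES = ("A", "G")


@dataclass(frozen=True)
class BlockSpec:
    """One LD block of the copying-chain process."""

    n_snps: int = 20
    rho: float = 0.95
    maf_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self):
        if not (0 <= self.rho <= 1):
            raise ValueError("copy probability rho must be in [0,1]")


@dataclass(frozen=True)
class PlantedLocus:
    block: int
    causal_index: int = 10
    beta: float = 0.3


@dataclass(frozen=True)
class DEGConfig:
    n_background_genes: int = 2000
    baseline_de_rate: float = 0.1
    odds_ratio: float = 3.0
    datasets: tuple[str, ...] = ("dataset1", "dataset2")


@dataclass(frozen=True)
class SCConfig:
    cell_types: tuple[str, ...] = ("SMC", "Fibroblast", "Endothelial")
    n_cells_per_type: int = 100
    module_genes_per_type: int = 40
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5    # NB size parameter r; var = mu + mu^2/r
    module_fold: float = 8.0
    n_genes_total: int = 2600     # > 2500 so a high-feature violator is constructible
    n_violators_per_reason: int = 5
    mito_mean: float = 8.0
    hb_mean: float = 0.1


@dataclass
class SimConfig:
    """Full configuration of the synthetic study.

    Defaults: 8 LD blocks of 20 SNPs (ρ=0.95) on chromosomes 1–8, five of
    them carrying a planted causal SNP (β=0.3); panel of 500 samples and a
    GWAS cohort of 5,000; per planted locus one positional, one eQTL and
    one chromatin target gene plus decoys; DEG odds ratio 3 over a
    2,000-gene background; three cell types × 100 cells with 40 module
    genes each at 8× fold change.
    """

    seed: int = 0
    n_samples_panel: int = 500
    n_gwas_cohort: int = 5000
    blocks: tuple[BlockSpec, ...] = tuple(BlockSpec() for _ in range(8))
    planted_loci: tuple[PlantedLocus, ...] = tuple(
        PlantedLocus(block=i) for i in range(5))
    block_start_pos: int = 1_000_000
    snp_spacing_bp: int = 1_000
    n_decoy_genes_per_block: int = 2
    deg: DEGConfig = field(default_factory=DEGConfig)
    sc: SCConfig = field(default_factory=SCConfig)
    n_signal_samples_per_group: int = 5
    signal_shift_sd: float = 3.0   # planted tumor-vs-control shift, in pooled SDs


@dataclass
class SimTruth:
    """Planted ground truth recorded alongside the generated files."""

    causal_snp_ids: list[str] = field(default_factory=list)
    causal_positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    block_spans: list[tuple[str, int, int]] = field(default_factory=list)
    planted_genes: dict[str, list[str]] = field(
        default_factory=lambda: {"positional": [], "eqtl": [], "chromatin": []})
    planted_direction: dict[str, str] = field(default_factory=dict)
    planted_modules: dict[str, str] = field(default_factory=dict)
    planted_pqtl_ids: list[str] = field(default_factory=list)
    violator_cells: dict[str, list[str]] = field(default_factory=dict)

    def all_planted_genes(self) -> set[str]:
        return set().union(*self.planted_genes.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

def _rngs(config: SimConfig, *names: str):
    children = np.random.SeedSequence(config.seed).spawn(10)
    slots = {"maf": 0, "panel": 1, "cohort": 2, "pheno": 3, "annot": 4,
             "deg": 5, "sc": 6, "signal": 7}
    return tuple(np.random.default_rng(children[slots[n]]) for n in names)


def snp_metadata(config: SimConfig) -> pd.DataFrame:
    """Deterministic SNP layout: ids, chromosome, position, MAF per block."""
    (rng,) = _rngs(config, "maf")
    rows = []
    for b, spec in enumerate(config.blocks):
        lo, hi = spec.maf_range
        mafs = rng.uniform(lo, hi, size=spec.n_snps)
        for k in range(spec.n_snps):
            rows.append({
                "snp_id": f"snp{b}_{k}",
                "chrom": str(b + 1),
                "pos": config.block_start_pos + k * config.snp_spacing_bp,
                "maf": mafs[k],
                "block": b,
            })
    return pd.DataFrame(rows)


def _simulate_dosages(config: SimConfig, meta: pd.DataFrame, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages (n × n_snps) from the per-block copying chain."""
    cols = []
    for b, spec in enumerate(config.blocks):
        mafs = meta.loc[meta["block"] == b, "maf"].to_numpy()
        hap = np.zeros((2, n, spec.n_snps), dtype=np.int8)
        for h in range(2):
            hap[h, :, 0] = rng.random(n) < mafs[0]
            for k in range(1, spec.n_snps):
                copy = rng.random(n) < spec.rho
                fresh = rng.random(n) < mafs[k]
                hap[h, :, k] = np.where(copy, hap[h, :, k - 1], fresh)
        cols.append(hap[0] + hap[1])
    return np.concatenate(cols, axis=1).astype(float)


def simulate_panel(config: SimConfig) -> GenotypePanel:
    """The LD reference panel drawn from the block copying-chain process."""
    meta = snp_metadata(config)
    (rng,) = _rngs(config, "panel")
    dosages = _simulate_dosages(config, meta, config.n_samples_panel, rng)
    return GenotypePanel(
        snp_ids=list(meta["snp_id"]),
        chroms=list(meta["chrom"]),
        positions=meta["pos"].to_numpy(),
        dosages=dosages,
        sample_ids=[f"panel_{i + 1}" for i in range(config.n_samples_panel)],
    )


def simulate_summary_stats(config: SimConfig) -> tuple[list[SummaryStatRecord], SimTruth]:
    """GWAS summary statistics from a fresh cohort with planted causal SNPs.

    The phenotype is y = Σ β·dosage + N(0,1); per-SNP P values come from
    the marginal simple-regression t test (df = n−2).
    """
    meta = snp_metadata(config)
    rng_c, rng_p = _rngs(config, "cohort", "pheno")
    g = _simulate_dosages(config, meta, config.n_gwas_cohort, rng_c)
    n = config.n_gwas_cohort

    truth = SimTruth()
    y = rng_p.normal(0.0, 1.0, size=n)
    causal_cols = []
    for pl in config.planted_loci:
        block_rows = meta.index[meta["block"] == pl.block]
        row = block_rows[pl.causal_index]
        causal_cols.append(row)
        y = y + pl.beta * g[:, row]
        sid = meta.loc[row, "snp_id"]
        truth.causal_snp_ids.append(sid)
        truth.causal_positions[sid] = (meta.loc[row, "chrom"], int(meta.loc[row, "pos"]))
    for b in sorted({pl.block for pl in config.planted_loci}):
        sub = meta[meta["block"] == b]
        truth.block_spans.append((str(sub["chrom"].iloc[0]),
                                  int(sub["pos"].min()), int(sub["pos"].max())))

    # vectorised marginal regression: t from the genotype-phenotype correlation
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sg = np.sqrt((gc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (gc.T @ yc) / (sg * sy)
    r = np.where(np.isfinite(r), np.clip(r, -1 + 1e-15, 1 - 1e-15), 0.0)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    from scipy import stats as sps
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    observed_maf = np.minimum(g.mean(axis=0) / 2, 1 - g.mean(axis=0) / 2)
    records = [
        SummaryStatRecord(
            snp_id=meta.loc[j, "snp_id"], chrom=meta.loc[j, "chrom"],
            pos=int(meta.loc[j, "pos"]),
            allele_ref=_CAUSAL_ALLELES[0], allele_alt=_CAUSAL_ALLELES[1],
            p=float(p[j]), maf=float(max(observed_maf[j], 1e-6)),
            beta=float(r[j] * sy / sg[j]) if sg[j] > 0 else 0.0,
        )
        for j in range(len(meta))
    ]
    return records, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class SimAnnotations:
    genes: list[GeneModel]
    eqtl: pd.DataFrame
    enhancers: list[IntervalRecord]
    interactions: pd.DataFrame
    pqtl: pd.DataFrame


def simulate_annotations(config: SimConfig, truth: SimTruth) -> SimAnnotations:
    """Gene models + eQTL/enhancer/interaction/pQTL tables with planted hits.

    Per planted locus: a positional target 2 kb from the causal SNP, an
    eQTL target 60 kb away (outside the positional window) with FDR < 0.05,
    and a chromatin target 200 kb away reached by an FDR < 1e-6 interaction
    from an enhancer over the causal SNP.  Decoy genes sit > 10 kb from all
    block SNPs; decoy eQTLs/interactions miss their FDR cutoffs or
    reference non-candidate SNPs; a planted pQTL sits 1 kb from each causal
    SNP and decoys > 20 kb from every block SNP.
    """
    (rng,) = _rngs(config, "annot")
    meta = snp_metadata(config)
    genes: list[GeneModel] = []
    eqtl_rows, interaction_rows, pqtl_rows = [], [], []
    enhancers: list[IntervalRecord] = []

    for i, pl in enumerate(config.planted_loci):
        sub = meta[meta["block"] == pl.block]
        chrom = str(sub["chrom"].iloc[0])
        causal_pos = int(sub["pos"].iloc[pl.causal_index])
        causal_id = sub["snp_id"].iloc[pl.causal_index]

        g_pos = GeneModel(f"gene_pos_{i}", f"POS{i}", chrom,
                          causal_pos + 2_000, causal_pos + 6_000, "+")
        g_eqtl = GeneModel(f"gene_eqtl_{i}", f"EQT{i}", chrom,
                           causal_pos + 60_000, causal_pos + 63_000, "+")
        strand = "+" if i % 2 == 0 else "-"
        g_hic = GeneModel(f"gene_hic_{i}", f"HIC{i}", chrom,
                          causal_pos + 200_000, causal_pos + 203_000, strand)
        genes += [g_pos, g_eqtl, g_hic]
        truth.planted_genes["positional"].append(g_pos.gene_id)
        truth.planted_genes["eqtl"].append(g_eqtl.gene_id)
        truth.planted_genes["chromatin"].append(g_hic.gene_id)

        eqtl_rows.append({"snp_id": causal_id, "gene_id": g_eqtl.gene_id,
                          "fdr": float(rng.uniform(0.001, 0.049)), "tissue": "uterus"})
        enhancers.append(IntervalRecord(chrom, causal_pos - 500, causal_pos + 500))
        interaction_rows.append({
            "chromA": chrom, "startA": causal_pos - 2_000, "endA": causal_pos + 2_000,
            "chromB": chrom, "startB": g_hic.tss - 1_000, "endB": g_hic.tss + 1_000,
            "fdr": 1e-8,
        })
        pqtl_id = f"pqtl_{i}"
        pqtl_rows.append({"variant_id": pqtl_id, "chrom": chrom,
                          "pos": causal_pos + 1_000, "protein": f"PROT{i}"})
        truth.planted_pqtl_ids.append(pqtl_id)

        # decoys anchored to this block
        eqtl_rows.append({"snp_id": causal_id, "gene_id": f"decoy_eqtl_{i}",
                          "fdr": float(rng.uniform(0.06, 0.9)), "tissue": "uterus"})
        genes.append(GeneModel(f"decoy_eqtl_{i}", f"DEQ{i}", chrom,
                               causal_pos + 80_000, causal_pos + 83_000, "+"))
        interaction_rows.append({   # right geometry, wrong FDR
            "chromA": chrom, "startA": causal_pos - 2_000, "endA": causal_pos + 2_000,
            "chromB": chrom, "startB": causal_pos + 300_000, "endB": causal_pos + 301_000,
            "fdr": 1e-5,
        })
        genes.append(GeneModel(f"decoy_hic_{i}", f"DHC{i}", chrom,
                               causal_pos + 300_000, causal_pos + 303_000, "+"))
        pqtl_rows.append({"variant_id": f"decoy_pqtl_{i}", "chrom": chrom,
                          "pos": causal_pos + 40_000, "protein": f"DECOY{i}"})

    # decoy genes away from every block and on null blocks
    for b, spec in enumerate(config.blocks):
        sub = meta[meta["block"] == b]
        chrom = str(sub["chrom"].iloc[0])
        left = int(sub["pos"].min()) - 60_000
        for j in range(config.n_decoy_genes_per_block):
            genes.append(GeneModel(f"decoy_gene_{b}_{j}", f"DG{b}_{j}", chrom,
                                   max(1, left - j * 20_000),
                                   max(1, left - j * 20_000) + 3_000, "+"))
        # eQTL on a non-candidate SNP of a null block: significant FDR but never mapped
        if b not in {pl.block for pl in config.planted_loci}:
            eqtl_rows.append({"snp_id": sub["snp_id"].iloc[0],
                              "gene_id": f"decoy_gene_{b}_0",
                              "fdr": 0.01, "tissue": "uterus"})

    return SimAnnotations(
        genes=genes,
        eqtl=pd.DataFrame(eqtl_rows),
        enhancers=enhancers,
        interactions=pd.DataFrame(interaction_rows),
        pqtl=pd.DataFrame(pqtl_rows),
    )


# ---------------------------------------------------------------------------
# DEG tables and single-cell counts
# ---------------------------------------------------------------------------

def simulate_deg_tables(config: SimConfig, truth: SimTruth,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, pd.DataFrame]:
    """DEG tables with a planted mapped-gene/DE-gene odds ratio.

    Planted target genes are DE with probability p1 and background genes
    with probability p0, where odds(p1)/odds(p0) equals the configured
    odds ratio.  Directions are assigned once per gene and reused across
    datasets, so no gene is significantly contradictory.
    """
    if rng is None:
        (rng,) = _rngs(config, "deg")
    planted = sorted(truth.all_planted_genes())
    background = [f"bg_gene_{j}" for j in range(config.deg.n_background_genes)]
    p0 = config.deg.baseline_de_rate
    odds0 = p0 / (1 - p0)
    odds1 = config.deg.odds_ratio * odds0
    p1 = odds1 / (1 + odds1)

    all_genes = np.array(planted + background)
    n = len(all_genes)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    for g, s in zip(planted, sign[:len(planted)]):
        truth.planted_direction[g] = "up" if s > 0 else "down"

    de_prob = np.full(n, p0)
    de_prob[:len(planted)] = p1
    tables = {}
    for ds in config.deg.datasets:
        de = rng.random(n) < de_prob
        fdr = np.where(de,
                       10 ** rng.uniform(-8, np.log10(0.049), n),
                       rng.uniform(0.05, 1.0, n))
        lfc = sign * np.where(de, rng.uniform(0.5, 3.0, n), rng.uniform(0.0, 0.5, n))
        tables[ds] = pd.DataFrame({"gene_id": all_genes, "log2fc": lfc,
                                   "fdr": fdr, "dataset": ds})
    return tables


def simulate_cell_matrix(config: SimConfig, truth: SimTruth,
                         rng: np.random.Generator | None = None) -> CellMatrix:
    """NB-distributed gene × cell counts with planted modules and QC violators.

    Module genes draw NB(mean × fold, r) in their home type and NB(mean, r)
    elsewhere.  Violating cells are appended with counts edited so each
    violates exactly one QC criterion, and recorded in the truth.
    """
    if rng is None:
        (rng,) = _rngs(config, "sc")
    sc = config.sc
    types = list(sc.cell_types)

    # gene roster: planted targets distributed round-robin + filler module
    # genes + background, then the marker genes the QC filter watches
    planted = sorted(truth.all_planted_genes())
    module_genes: dict[str, list[str]] = {t: [] for t in types}
    for i, g in enumerate(planted):
        module_genes[types[i % len(types)]].append(g)
    for t in types:
        need = sc.module_genes_per_type - len(module_genes[t])
        module_genes[t] += [f"mod_{t}_{j}" for j in range(max(0, need))]
    markers = [f"MT-G{j}" for j in range(1, 14)] + ["HBA1", "HBA2", "HBB",
                                                    "EPCAM", "KRT18"]
    named = [g for t in types for g in module_genes[t]]
    n_bg = sc.n_genes_total - len(named) - len(markers)
    genes = named + [f"sc_bg_{j}" for j in range(max(0, n_bg))] + markers
    gene_index = {g: i for i, g in enumerate(genes)}
    for t in types:
        for g in module_genes[t]:
            truth.planted_modules[g] = t

    def nb(mean, size):
        r = sc.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean), size=size)

    n_clean = sc.n_cells_per_type * len(types)
    counts = nb(sc.nb_mean, (len(genes), n_clean)).astype(float)
    labels = [t for t in types for _ in range(sc.n_cells_per_type)]
    label_arr = np.asarray(labels)
    for t in types:
        cols = label_arr == t
        rows = [gene_index[g] for g in module_genes[t]]
        counts[np.ix_(rows, cols)] = nb(sc.nb_mean * sc.module_fold,
                                        (len(rows), int(cols.sum())))
    # markers in clean cells: modest mito, trace HB, zero epithelial
    mito_rows = [gene_index[g] for g in genes if g.startswith("MT-")]
    hb_rows = [gene_index[g] for g in ("HBA1", "HBA2", "HBB")]
    epi_rows = [gene_index[g] for g in ("EPCAM", "KRT18")]
    counts[mito_rows, :] = nb(sc.mito_mean, (len(mito_rows), n_clean))
    counts[hb_rows, :] = nb(sc.hb_mean, (len(hb_rows), n_clean))
    counts[epi_rows, :] = 0.0

    cell_names = [f"cell_{t}_{j}" for t in types for j in range(sc.n_cells_per_type)]

    # constructed violators: each breaks exactly one criterion
    viol_cols, viol_names, viol_labels = [], [], []
    truth.violator_cells = {k: [] for k in
                            ("features_low", "features_high", "mito", "hb", "epithelial")}

    def add(reason, col):
        name = f"viol_{reason}_{len(truth.violator_cells[reason]) + 1}"
        truth.violator_cells[reason].append(name)
        viol_cols.append(col)
        viol_names.append(name)
        viol_labels.append(types[0])

    nonmarker = [i for i in range(len(genes))
                 if i not in set(mito_rows) | set(hb_rows) | set(epi_rows)]
    for _ in range(sc.n_violators_per_reason):
        col = np.zeros(len(genes))
        col[nonmarker[:150]] = 1.0
        add("features_low", col)

        col = np.zeros(len(genes))
        col[nonmarker] = 1.0
        col[mito_rows] = 1.0
        col[hb_rows] = 1.0
        add("features_high", col)

        base = nb(sc.nb_mean, len(genes)).astype(float)
        base[epi_rows] = 0.0
        base[hb_rows] = 0.0
        base[mito_rows] = np.ceil(0.15 * base.sum() / len(mito_rows))
        add("mito", base)

        base = nb(sc.nb_mean, len(genes)).astype(float)
        base[epi_rows] = 0.0
        base[mito_rows] = 1.0
        base[hb_rows] = np.ceil(0.02 * base.sum())
        add("hb", base)

        base = nb(sc.nb_mean, len(genes)).astype(float)
        base[hb_rows] = 0.0
        base[mito_rows] = 1.0
        base[epi_rows] = [2.0, 1.0]
        add("epithelial", base)

    if viol_cols:
        counts = np.concatenate([counts, np.column_stack(viol_cols)], axis=1)
        cell_names += viol_names
        labels += viol_labels
    return CellMatrix(counts=counts, gene_names=genes,
                      cell_names=cell_names, labels=labels)


def simulate_deg_and_sc(config: SimConfig, truth: SimTruth
                        ) -> tuple[dict[str, pd.DataFrame], CellMatrix]:
    """Both DEG tables and the labelled single-cell count matrix."""
    return simulate_deg_tables(config, truth), simulate_cell_matrix(config, truth)


def simulate_signal_tables(config: SimConfig, truth: SimTruth
                           ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-gene per-sample H3K27ac-like and Hi-C-like signal tables.

    Baseline N(10,1) per gene and sample, with the planted target genes
    shifted upward in the tumor group by ``signal_shift_sd`` pooled SDs.
    Returns the tables and the per-sample group labels.
    """
    (rng,) = _rngs(config, "signal")
    n = config.n_signal_samples_per_group
    groups = ["tumor"] * n + ["control"] * n
    samples = [f"PT{900 + i}_{g}" for i, g in enumerate(groups)]
    genes = sorted(truth.all_planted_genes())
    tables = {}
    for name in ("h3k27ac", "hic"):
        base = rng.normal(10.0, 1.0, size=(len(genes), 2 * n))
        base[:, :n] += config.signal_shift_sd   # tumor group carries the shift
        tables[name] = pd.DataFrame(base, index=pd.Index(genes, name="gene_id"),
                                    columns=samples)
    return tables, groups


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig):
    """Generate every pipeline input in memory; returns (inputs dict, truth)."""
    panel = simulate_panel(config)
    stats, truth = simulate_summary_stats(config)
    ann = simulate_annotations(config, truth)
    deg_tables, cell_matrix = simulate_deg_and_sc(config, truth)
    signal_tables, groups = simulate_signal_tables(config, truth)
    inputs = {
        "stats": stats, "panel": panel, "genes": ann.genes, "eqtl": ann.eqtl,
        "enhancers": ann.enhancers, "interactions": ann.interactions,
        "pqtl": ann.pqtl, "deg_tables": deg_tables, "cell_matrix": cell_matrix,
        "signal_tables": signal_tables, "signal_groups": groups,
    }
    return inputs, truth


def write_all(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Write every generated input as standard-format files + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs, truth = simulate_all(config)
    write_summary_stats(inputs["stats"], outdir / "summary_stats.tsv")
    write_dosage_panel(inputs["panel"], outdir / "panel_dosages.tsv",
                       outdir / "panel_sites.tsv")
    write_gene_models(inputs["genes"], outdir / "genes.tsv")
    inputs["eqtl"].to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
    write_intervals(inputs["enhancers"], outdir / "enhancers.bed", BED_0HALF)
    inter = inputs["interactions"].copy()
    inter["startA"] -= 1   # BEDPE-like files are 0-based half-open
    inter["startB"] -= 1
    inter.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    inputs["pqtl"].to_csv(outdir / "pqtl.tsv", sep="\t", index=False)
    for name, table in inputs["deg_tables"].items():
        table.to_csv(outdir / f"deg_{name}.tsv", sep="\t", index=False)
    cm = inputs["cell_matrix"]
    write_expression_matrix(cm.counts, cm.gene_names, cm.cell_names,
                            outdir / "sc_counts.tsv")
    pd.DataFrame({"cell": cm.cell_names, "cell_type": cm.labels}).to_csv(
        outdir / "sc_labels.tsv", sep="\t", index=False)
    for name, table in inputs["signal_tables"].items():
        table.to_csv(outdir / f"signal_{name}.tsv", sep="\t")
    pd.DataFrame({"sample": inputs["signal_tables"]["h3k27ac"].columns,
                  "group": inputs["signal_groups"]}).to_csv(
        outdir / "signal_groups.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return truth
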