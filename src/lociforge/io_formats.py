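"""Readers and writers for every external table the pipeline touches.

All coordinates are converted to a single internal convention on ingest:
**1-based, closed (inclusive) intervals**, matching GWAS summary statistics
and gene-model conventions.  Only this module converts; everything
downstream assumes internal coordinates.  BED input (0-based, half-open)
is shifted on read and shifted back on write.

Chromosome names are normalised with :func:`normalize_chrom`; mixing
``chr1`` and ``1`` across input files is a hard error upstream, never a
silent empty join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

BED_0HALF = "bed_0half"
ONE_INCLUSIVE = "one_inclusive"


def normalize_chrom(name: str, style: str = "bare") -> str:
    """Normalise a chromosome name to ``bare`` (``1``) or ``chr`` (``chr1``) style."""
    s = str(name).strip()
    bare = s[3:] if s.lower().startswith("chr") else s
    if style == "bare":
        return bare
    if style == "chr":
        return "chr" + bare
    raise ValueError(f"unknown chromosome style {style!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS association: SNP id, position (1-based) and P value."""

    snp_id: str
    chrom: str
    pos: int
    allele_ref: str
    allele_alt: str
    p: float
    maf: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.snp_id}: P must be in (0,1], got {self.p}")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF must be in (0,0.5], got {self.maf}")


@dataclass
class GenotypePanel:
    """LD reference panel: sample × SNP dosage matrix (0/1/2, NaN = missing).

    Missing dosages are mean-imputed per SNP *only* when computing r²;
    the stored matrix is never modified.
    """

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray          # 1-based, int
    dosages: np.ndarray            # float (n_samples, n_snps), NaN allowed
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n = len(self.snp_ids)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != n:
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1] if self.dosages.ndim == 2 else '?'}"
                f" columns for {n} SNPs"
            )
        if len(self.chroms) != n or len(self.positions) != n:
            raise ValueError("snp_ids, chroms and positions must have equal length")
        finite = ~np.isnan(self.dosages)
        vals = self.dosages[finite]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1 or 2 (NaN for missing)")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def imputed_dosages(self, cols: Sequence[int] | None = None) -> np.ndarray:
        """Dosage columns with missing values replaced by the per-SNP mean."""
        x = self.dosages if cols is None else self.dosages[:, cols]
        x = np.array(x, dtype=float)
        nan = np.isnan(x)
        if nan.any():
            means = np.nanmean(np.where(nan, np.nan, x), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            x[nan] = np.take(means, np.nonzero(nan)[1])
        return x

    def monomorphic_mask(self) -> np.ndarray:
        """True for SNPs with fewer than 2 distinct observed dosage values."""
        out = np.zeros(self.n_snps, dtype=bool)
        for j in range(self.n_snps):
            col = self.dosages[:, j]
            obs = col[~np.isnan(col)]
            out[j] = np.unique(obs).size < 2
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its strand-resolved transcription start site."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval held in internal 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "IntervalRecord") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_DEFAULT_STATS_COLUMNS = {
    "snp_id": "snp_id", "chrom": "chrom", "pos": "pos",
    "allele_ref": "allele_ref", "allele_alt": "allele_alt", "p": "p",
}


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    zero_based_positions: bool = False,
    chrom_style: str = "bare",
) -> list[SummaryStatRecord]:
    """Read delimited GWAS summary statistics into validated records.

    ``column_map`` maps canonical field names (``snp_id``, ``chrom``, ``pos``,
    ``allele_ref``, ``allele_alt``, ``p``, optionally ``maf``, ``beta``) to the
    file's header names.  Rows whose P value does not parse are dropped with a
    logged count; a missing mandatory column or a duplicated SNP id is a hard
    error.  Positions written 0-based are shifted +1 when the flag is set.
    """
    cmap = dict(_DEFAULT_STATS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for canon in _DEFAULT_STATS_COLUMNS:
        if cmap[canon] not in df.columns:
            raise ValueError(f"summary statistics file missing mandatory column {cmap[canon]!r}")

    p = pd.to_numeric(df[cmap["p"]], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    if bad.any():
        logger.warning("dropped %d rows with non-parsable or out-of-range P", int(bad.sum()))
    df = df.loc[~bad].reset_index(drop=True)
    p = p.loc[~bad].reset_index(drop=True)

    ids = df[cmap["snp_id"]]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique()
        raise ValueError(f"duplicate snp_id in summary statistics: {dups[:5].tolist()}")

    pos = pd.to_numeric(df[cmap["pos"]]).astype(np.int64)
    if zero_based_positions:
        pos = pos + 1
    maf = (pd.to_numeric(df[cmap["maf"]], errors="coerce")
           if "maf" in cmap and cmap["maf"] in df.columns else None)
    beta = (pd.to_numeric(df[cmap["beta"]], errors="coerce")
            if "beta" in cmap and cmap["beta"] in df.columns else None)

    records = []
    for i in range(len(df)):
        records.append(SummaryStatRecord(
            snp_id=str(ids.iloc[i]),
            chrom=normalize_chrom(df[cmap["chrom"]].iloc[i], chrom_style),
            pos=int(pos.iloc[i]),
            allele_ref=str(df[cmap["allele_ref"]].iloc[i]),
            allele_alt=str(df[cmap["allele_alt"]].iloc[i]),
            p=float(p.iloc[i]),
            maf=None if maf is None or pd.isna(maf.iloc[i]) else float(maf.iloc[i]),
            beta=None if beta is None or pd.isna(beta.iloc[i]) else float(beta.iloc[i]),
        ))
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    rows = [{
        "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
        "allele_ref": r.allele_ref, "allele_alt": r.allele_alt,
        "p": repr(r.p),
        "maf": "" if r.maf is None else repr(r.maf),
        "beta": "" if r.beta is None else repr(r.beta),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED enhancers, generic interval tables)
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | Path,
    convention: str,
    chrom_style: str = "bare",
) -> list[IntervalRecord]:
    """Read a 3+ column interval file into internal 1-based inclusive records.

    ``bed_0half`` intervals ``[s, e)`` become ``[s+1, e]``; ``one_inclusive``
    files pass through.  A BED record with ``end <= start`` (an empty
    interval) is rejected with its line number logged.
    """
    if convention not in (BED_0HALF, ONE_INCLUSIVE):
        raise ValueError(f"unknown interval convention {convention!r}")
    out: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, s, e = normalize_chrom(fields[0], chrom_style), int(fields[1]), int(fields[2])
            if convention == BED_0HALF:
                if e <= s:
                    logger.warning("line %d: rejected empty/negative BED interval %s:%d-%d",
                                   lineno, chrom, s, e)
                    continue
                out.append(IntervalRecord(chrom, s + 1, e))
            else:
                if e < s:
                    logger.warning("line %d: rejected interval with end < start", lineno)
                    continue
                out.append(IntervalRecord(chrom, s, e))
    return out


def write_intervals(records: Iterable[IntervalRecord], path: str | Path, convention: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            if convention == BED_0HALF:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
            elif convention == ONE_INCLUSIVE:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                raise ValueError(f"unknown interval convention {convention!r}")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, chrom_style: str = "bare") -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, symbol, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"gene model file missing column {col!r}")
    return [
        GeneModel(
            gene_id=row.gene_id, symbol=row.symbol,
            chrom=normalize_chrom(row.chrom, chrom_style),
            start=int(row.start), end=int(row.end), strand=row.strand,
        )
        for row in df.itertuples()
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame([{
        "gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
        "start": g.start, "end": g.end, "strand": g.strand,
    } for g in genes]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simple annotation tables (validated DataFrames)
# ---------------------------------------------------------------------------

def _read_table(path, required, numeric=(), chrom_cols=(), chrom_style="bare"):
    df = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    for col in numeric:
        df[col] = pd.to_numeric(df[col])
    for col in chrom_cols:
        df[col] = df[col].map(lambda c: normalize_chrom(c, chrom_style))
    return df


def read_eqtl_table(path: str | Path, chrom_style: str = "bare") -> pd.DataFrame:
    """eQTL records: snp_id, gene_id, fdr and an optional tissue label."""
    df = _read_table(path, ["snp_id", "gene_id", "fdr"], numeric=["fdr"])
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("eQTL FDR outside [0,1]")
    if "tissue" not in df.columns:
        df["tissue"] = "unspecified"
    return df


def read_interaction_table(path: str | Path, chrom_style: str = "bare") -> pd.DataFrame:
    """BEDPE-like chromatin interactions: two anchors (0-based half-open) + FDR.

    Columns chromA,startA,endA,chromB,startB,endB,fdr; anchor coordinates are
    converted to internal 1-based inclusive on read.
    """
    df = _read_table(
        path, ["chromA", "startA", "endA", "chromB", "startB", "endB", "fdr"],
        numeric=["startA", "endA", "startB", "endB", "fdr"],
        chrom_cols=["chromA", "chromB"], chrom_style=chrom_style,
    )
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("interaction FDR outside [0,1]")
    df["startA"] += 1
    df["startB"] += 1
    return df


def read_pqtl_table(path: str | Path, chrom_style: str = "bare") -> pd.DataFrame:
    """pQTL variants: variant_id, chrom, pos (1-based), protein."""
    df = _read_table(path, ["variant_id", "chrom", "pos", "protein"],
                     numeric=["pos"], chrom_cols=["chrom"], chrom_style=chrom_style)
    if (df["pos"] < 1).any():
        raise ValueError("pQTL position < 1")
    return df


def read_deg_table(path: str | Path, dataset: str | None = None) -> pd.DataFrame:
    """A differential-expression table: gene_id, log2fc, fdr (+ dataset label)."""
    df = _read_table(path, ["gene_id", "log2fc", "fdr"], numeric=["log2fc", "fdr"])
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("DEG FDR outside [0,1]")
    if dataset is not None:
        df["dataset"] = dataset
    elif "dataset" not in df.columns:
        df["dataset"] = Path(path).stem
    return df


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_by_cells",
    gene_names_path: str | Path | None = None,
    cell_names_path: str | Path | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a dense TSV or matrix-market triplet file as genes × cells.

    Dense files carry row/column names; matrix-market files take optional
    one-name-per-line sidecars (defaults ``g1..`` / ``c1..``).  Negative
    values are a hard error; duplicated gene names are suffix-deduplicated
    with a warning.  Returns ``(matrix, gene_names, cell_names)`` in
    canonical genes × cells orientation.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if path.suffix == ".mtx" or path.name.endswith(".mtx.gz"):
        mat = np.asarray(mmread(path).todense(), dtype=float)
        rows = (_read_names(gene_names_path, mat.shape[0], "g")
                if orientation == "genes_by_cells"
                else _read_names(cell_names_path, mat.shape[0], "c"))
        cols = (_read_names(cell_names_path, mat.shape[1], "c")
                if orientation == "genes_by_cells"
                else _read_names(gene_names_path, mat.shape[1], "g"))
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
        rows, cols = [str(x) for x in df.index], [str(x) for x in df.columns]

    if orientation == "cells_by_genes":
        mat = mat.T
        genes, cells = cols, rows
    else:
        genes, cells = rows, cols
    if (mat < 0).any():
        raise ValueError("expression matrix contains negative values")
    genes = _dedup_names(genes)
    return mat, genes, cells


def _read_names(path, n, prefix):
    if path is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    names = [ln.strip() for ln in open(path) if ln.strip()]
    if len(names) != n:
        raise ValueError(f"{path}: expected {n} names, found {len(names)}")
    return names


def _dedup_names(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    dup = 0
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
            dup += 1
        else:
            seen[name] = 0
            out.append(name)
    if dup:
        logger.warning("suffix-deduplicated %d duplicated gene names", dup)
    return out


def write_expression_matrix(mat: np.ndarray, genes, cells, path: str | Path) -> None:
    pd.DataFrame(mat, index=genes, columns=cells).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

def read_dosage_panel(
    dosage_path: str | Path,
    sites_path: str | Path,
    chrom_style: str = "bare",
) -> GenotypePanel:
    """Read a sample × SNP dosage TSV plus its SNP-site table.

    The dosage file has a ``sample_id`` first column and one column per SNP;
    the sites TSV has columns snp_id, chrom, pos and fixes SNP order.
    Missing dosages are empty/NA cells.
    """
    sites = _read_table(sites_path, ["snp_id", "chrom", "pos"],
                        numeric=["pos"], chrom_cols=["chrom"], chrom_style=chrom_style)
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    missing = [s for s in sites["snp_id"] if s not in df.columns]
    if missing:
        raise ValueError(f"dosage file missing SNP columns: {missing[:5]}")
    dos = df[list(sites["snp_id"])].to_numpy(dtype=float)
    panel = GenotypePanel(
        snp_ids=list(sites["snp_id"].astype(str)),
        chroms=list(sites["chrom"].astype(str)),
        positions=sites["pos"].to_numpy(),
        dosages=dos,
        sample_ids=[str(i) for i in df.index],
    )
    mono = panel.monomorphic_mask()
    if mono.any():
        logger.warning("panel contains %d monomorphic SNPs", int(mono.sum()))
    return panel


def write_dosage_panel(panel: GenotypePanel, dosage_path: str | Path,
                       sites_path: str | Path) -> None:
    pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": panel.chroms, "pos": panel.positions,
    }).to_csv(sites_path, sep="\t", index=False)
    samples = panel.sample_ids or [f"s{i + 1}" for i in range(panel.n_samples)]
    df = pd.DataFrame(panel.dosages, index=samples, columns=panel.snp_ids)
    # keep dosages integral in the file; NaN -> empty cell
    df.to_csv(dosage_path, sep="\t", index_label="sample_id", float_format="%.0f")
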