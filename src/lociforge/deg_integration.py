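"""Intersect mapped genes with differential-expression tables and test enrichment.

Per dataset, the 2×2 table crosses mapped / not-mapped with differentially
expressed / not (universe = all genes in that dataset's table).  The odds
ratio is the cross-product ratio a·d / (b·c) and the two-sided P is the
exact Fisher probability: the sum over the hypergeometric support of all
tables (at the observed margins) whose probability does not exceed the
observed table's.  The enumeration is done in exact integer arithmetic
(binomial coefficients compared as integers), so tied tables are included
deterministically; scipy's implementation is used as an independent
cross-check in the test suite, not here.

Direction calls: a gene is *up* (*down*) when significant (FDR < 0.05)
with positive (negative) log2 fold change in at least one dataset and not
significant with the opposite sign in another; significant opposite signs
in two datasets flag a contradiction and exclude the gene from both
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ld_clump import Thresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    fdr: float
    dataset: str

    def __post_init__(self):
        if not (0 <= self.fdr <= 1):
            raise ValueError(f"{self.gene_id}: FDR must be in [0,1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """2×2 enrichment table: a=mapped∩DE, b=mapped∩notDE, c=notMapped∩DE, d=rest."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(
    mapped_gene_ids,
    deg_tables: dict[str, pd.DataFrame],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene direction label over one or more DEG tables.

    Returns a frame with columns gene_id, direction ∈ {up, down, none},
    contradiction (bool), and the datasets supporting each sign.
    """
    if not deg_tables:
        raise ValueError("at least one DEG table required")
    rows = []
    for gene in sorted(set(mapped_gene_ids)):
        up_in, down_in = [], []
        for name, table in deg_tables.items():
            sub = table[table["gene_id"] == gene]
            for r in sub.itertuples():
                if r.fdr < thresholds.deg_fdr:
                    (up_in if r.log2fc > 0 else down_in).append(name)
        contradiction = bool(up_in) and bool(down_in)
        if contradiction:
            direction = "none"
            logger.warning("gene %s has contradictory significant directions (%s vs %s)",
                           gene, up_in, down_in)
        elif up_in:
            direction = "up"
        elif down_in:
            direction = "down"
        else:
            direction = "none"
        rows.append({"gene_id": gene, "direction": direction,
                     "contradiction": contradiction,
                     "up_datasets": ";".join(up_in), "down_datasets": ";".join(down_in)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher exact enrichment
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher P by integer hypergeometric enumeration.

    All tables with the observed margins whose probability is <= the
    observed table's probability contribute; the tie comparison is made on
    integer binomial products, so it is exact.
    """
    r1, k, n = a + b, a + c, a + b + c + d
    obs = comb(k, a) * comb(n - k, r1 - a)
    total = 0
    for x in range(max(0, r1 - (n - k)), min(r1, k) + 1):
        w = comb(k, x) * comb(n - k, r1 - x)
        if w <= obs:
            total += w
    return float(Fraction(total, comb(n, r1)))


def fisher_enrichment(mapped_set, de_set, universe) -> EnrichmentResult:
    """Fisher exact test of mapped-gene × DE-gene overlap within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    mapped, de = set(mapped_set), set(de_set)
    if not mapped <= universe or not de <= universe:
        raise ValueError("mapped_set and de_set must be subsets of the universe")
    a = len(mapped & de)
    b = len(mapped - de)
    c = len(de - mapped)
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else (0.0 if c or b else float("nan"))
    else:
        odds = (a * d) / (b * c)
    p = fisher_exact_two_sided(a, b, c, d)
    return EnrichmentResult(a, b, c, d, odds, p)


def enrichment_by_dataset(
    mapped_gene_ids,
    deg_tables: dict[str, pd.DataFrame],
    thresholds: Thresholds = Thresholds(),
) -> dict[str, EnrichmentResult]:
    """One Fisher test per dataset, universe = that dataset's gene list.

    Mapped genes absent from a dataset's universe are dropped from that
    dataset's test with a logged count.
    """
    mapped = set(mapped_gene_ids)
    out = {}
    for name, table in deg_tables.items():
        universe = set(table["gene_id"])
        de = set(table.loc[table["fdr"] < thresholds.deg_fdr, "gene_id"])
        dropped = mapped - universe
        if dropped:
            logger.warning("dataset %s: %d mapped genes absent from the universe, dropped",
                           name, len(dropped))
        out[name] = fisher_enrichment(mapped & universe, de, universe)
    return out


def enrichment_frame(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "dataset": name, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "p_two_sided": r.p_two_sided,
    } for name, r in results.items()])
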