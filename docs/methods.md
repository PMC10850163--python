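# Methods

This note documents the models, conventions and numerical choices behind
lociforge, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Coordinates and formats

All internal coordinates are 1-based inclusive. Only the io layer
converts: BED and BEDPE-like inputs (0-based half-open) are shifted on
read (`[s, e)` → `[s+1, e]`) and shifted back on write, which makes the
conversion an involution and confines off-by-one risk to one module.
Interval overlap means ≥ 1 shared base between closed intervals.
Chromosome names are normalised by stripping/adding the `chr` prefix;
mixed naming across files is surfaced rather than silently producing
empty joins.

## LD and clumping

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD); the panel format is unphased, so no attempt is made to
phase haplotypes. Missing dosages are mean-imputed per SNP for the
correlation only — the stored matrix is never modified. A monomorphic
SNP is defined unlinkable (r² = 0, warned) rather than NaN, so it can
never tag or be tagged. Inter-chromosomal r² is never computed (treated
as 0).

The greedy classification walks significant SNPs in ascending-P order
with ties broken by ascending position then lexicographic id; this
tie-break is a determinism choice, since the selection order is otherwise
platform-dependent when P values collide. Thresholds are asymmetric by
design: independence requires r² **< 0.8** while candidacy requires r²
**> 0.8**, so a pair at exactly 0.8 satisfies neither. Significant SNPs
absent from the reference panel are kept as independent-significant
singletons (with a logged count) instead of silently dropped, because
dropping them would delete entire loci; their LD to everything is taken
as 0. Candidate status is restricted to SNPs present in the GWAS file —
panel-only SNPs are never promoted.

Risk loci are the connected components of a graph over independent
significant SNPs: an edge joins two on the same chromosome when their r²
≥ 0.1 **or** the gap between their LD blocks is < 250 kb. Transitive
merging means a chain of blocks 200 kb apart forms one locus even when
its ends are 400 kb apart. The construction is idempotent: no pair of
final loci can satisfy the merge condition, since such a pair would have
been one component.

## Gene mapping

Positional distance is measured to the gene body (not the TSS), 0 inside
`[start, end]`, inclusive at exactly 10 kb — gene-boundary distance is
the convention of standard positional mappers and the window is otherwise
underdetermined. eQTL joins require the SNP to be a *candidate* SNP (a
config-visible alternative would accept any SNP inside the locus
interval; candidate SNPs are the stricter, LD-justified reading). The
promoter window is −250/+500 bp of the strand-resolved TSS, reflected on
the − strand and clipped at position 1. Chromatin mapping tests both
anchor orientations, since BEDPE anchors carry no order; the SNP-side
anchor must contain a candidate SNP lying inside an enhancer interval and
the other anchor must overlap the promoter window, with interaction
FDR < 10⁻⁶ strict. A gene reached from several loci accumulates all
source locus ids.

## Locus annotation

pQTL proximity is |pos − lead pos| ≤ 20 kb, inclusive at the boundary;
per-locus counts deduplicate variants shared between leads. Per-locus
signal (H3K27ac intensity or Hi-C contact strength, supplied as a
pre-aggregated gene × sample table; track extraction is out of scope) is
the unweighted mean over member genes, since no weighting scheme is
implied by a single per-locus intensity. The group comparison is a
pooled-variance two-sided Student *t* (df = n₁+n₂−2); Welch's form is
available as a switch but not default. Zero pooled variance with equal
means returns t = 0, P = 1. No multiple-testing correction is applied
across loci by default; `bh_fdr` is available if wanted.

## Enrichment statistics

The 2×2 odds ratio is the cross-product ratio a·d/(b·c) (+∞ when
b·c = 0 and a·d > 0), not the conditional maximum-likelihood estimate
some packages print — the closed form is reproducible and the difference
is small away from extreme tables. The two-sided P sums, over the
hypergeometric support at the observed margins, the probabilities of all
tables no more probable than the observed one. The tie comparison is
made on exact integer binomial products (`math.comb`), so tables with
exactly equal probability are included deterministically; the sum is
converted to float once at the end. This costs ~10 ms at a universe of
15,000 genes. Benjamini–Hochberg adjustment is delegated to statsmodels.

Direction calls label a gene up (down) when significant with positive
(negative) log2FC in ≥ 1 dataset and not significant with the opposite
sign elsewhere; significant opposite signs flag a contradiction and
exclude the gene from both counts.

## Single-cell stage

QC keeps a cell iff 200 ≤ features ≤ 2500 (inclusive — the removal rule
targets "fewer than 200 or greater than 2500"), mito ≤ 7%, haemoglobin
(HBA1/HBA2/HBB) ≤ 1%, and EPCAM/KRT18 undetected, where "detectable"
is defined as raw count ≥ 1. The filter is a per-cell predicate, hence
order-independent and idempotent. Missing marker genes disable their
criterion with a warning.

Profiles are computed on CP10K/log1p-normalised counts — the upstream
variance-stabilising transform of the original single-cell toolchain is
not reimplemented, and CP10K/log1p is the conventional stand-in,
switchable off via `normalize=False`. Row z-scores use the sample SD
(ddof = 1, the `scale="row"` convention); constant rows are excluded
(module "none"). Module ties resolve to the lexicographically first cell
type and are flagged. Percent-expressing counts raw nonzeros.
Clustering, integration and embedding are not reimplemented; cell-type
labels are an input.

## Synthetic data: what it emulates and what it does not

The panel uses a first-order copying chain: within a block, SNP k+1
copies SNP k's haplotype allele with probability ρ, else redraws from its
MAF; the diploid dosage sums two independent haplotypes. Adjacent
haplotype r² is ≈ ρ² in expectation, so LD decay is directly tunable and
verifiable; a coalescent simulation would be more realistic but harder to
reason about, and block LD is what clumping exercises. GWAS P values
come from marginal simple regression of a quantitative phenotype
y = Σ β·g + N(0,1) on a **freshly simulated cohort**, so panel r² and
association strength are decoupled as in real data. Defaults: 8 blocks
of 20 SNPs (ρ = 0.95, MAF ∈ [0.1, 0.5], 1 kb spacing) on chromosomes
1–8, five blocks carrying a causal SNP at β = 0.3, cohort n = 5,000,
panel n = 500 — at these values the causal SNP's expected association is
far beyond genome-wide significance while the panel is small enough for
sub-second simulation.

Annotations are constructed, not sampled near thresholds: planted eQTL
FDRs are drawn strictly below 0.05 and decoys at ≥ 0.05; planted
interactions get FDR 10⁻⁸ and decoys 10⁻⁵; planted pQTLs sit 1 kb from
the causal SNP (within ±20 kb of *any* block SNP, so the count is robust
to which block member becomes lead) and decoys > 20 kb from every block
SNP. DEG membership is Bernoulli with odds multiplied by the configured
odds ratio for planted genes; directions are drawn once per gene and
shared across datasets, so contradictions cannot arise. Single-cell
counts are NB(mean, dispersion) with a shared dispersion, module genes at
mean × 8 in their home type; QC violators are appended with counts edited
deterministically so each breaks exactly one criterion. The gene roster
is 2,600 genes so that a > 2,500-feature violator is constructible while
clean cells (~1,500–2,300 features) stay inside the bounds.

What the generator does **not** emulate: realistic allele-frequency
spectra, case-control liability, LD between blocks, batch effects,
doublets, or count depth variation between cell types. Passing tests
therefore demonstrate correctness of the decision rules and calibration
of the statistics under the stated generative model, not performance on
real cohort data.

## Problem sizes and tolerances

The test suite verifies clumping against an independently coded
brute-force oracle on 200 random instances of ≤ 50 SNPs; planted-locus
recovery over 100 replicates at cohort 5,000 / panel 500; the Fisher
implementation against an exact-rational enumeration on every 2×2 table
with total ≤ 30 (tolerance 10⁻¹²) and against scipy as an independent
cross-check; odds-ratio calibration over 200 replicates at a universe of
15,000 genes; and module recovery on the default single-cell matrix.
The acceptance script uses 25 locus-recovery and 2 × 100 odds-ratio
replicates, sizes chosen to keep a full run in seconds while leaving
Monte-Carlo error well inside the calibration bands. Floating-point
round-trips are asserted to 10⁻¹² for floats and exactly for integers.

## Known limitations

- The clumping walk is O(n²) in significant SNPs per chromosome; it is
  meant for post-threshold SNP sets, not the full 10⁷-SNP genome scan.
- r² from dosages underestimates haplotype LD when phasing matters;
  panels with phase information are not exploited.
- The eQTL channel trusts the input FDRs; no tissue weighting or
  colocalisation is attempted.
- Locus signal aggregation assumes member genes are a fair summary of
  the locus; peak-level aggregation would need upstream peak calls.
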