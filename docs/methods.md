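# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind pausekit's three analysis tracks and its
synthetic-data generators.

## Coordinates, regions and densities

All internal coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Each gene carries a single TSS/TES pair (gene-level model;
isoform-resolved TSS selection is out of scope). The promoter window is
−30 bp/+300 bp around the TSS *in transcription direction*: for a minus-strand
gene the window is mirrored genomically, the only biologically coherent
reading of a strand-asymmetric window. The gene body is the remaining gene
length; genes no longer than the downstream window (≤300 bp) have an empty
body and are flagged TR-ineligible rather than rejected.

Region density is mean per-base fragment coverage per million mapped
fragments (per-bp BPM): density = (Σ coverage / region length) × 10⁶ /
total fragments. A per-bp (rather than per-region or fixed-bin) unit makes
promoter and body densities directly comparable, which the TR ratio requires;
it is invariant to splitting a region and recombining by length-weighted
mean, and to multiplying coverage and library size by a common factor.

Peak-to-gene assignment selects genes whose interval lies within 100 kb of a
peak, with a closed bound (a gene at exactly 100 kb is selected) and
distance 0 on overlap.

## Traveling ratio and tangent classification

TR = promoter density / body density, computed only for eligible genes:
non-empty body, body density strictly positive, promoter density at or above
a configurable floor (default 0, i.e. any signal). Genes with zero body
density are excluded rather than given a pseudocount — a pseudocount would
manufacture finite TRs for fully paused genes and distort the curve tails;
exclusions are retained in the table with a reason code.

The two-condition comparison ranks genes by ΔTR = TR₁ − TR₂ ascending (ties
broken by gene id for determinism). Tangent detection needs a scaling
convention for "slope 1" to be meaningful in arbitrary units: both axes are
rescaled to [0, 1] (rank → rank/(n−1), ΔTR min–max normalized), the same
convention used by rank-curve knee methods. The local slope is a centered
finite difference across an odd smoothing window (default 11 points);
`cut_hi` is the smallest upper-half index where the slope crosses from ≤1 to
>1 and stays above 1 for at least a window. `cut_lo` is defined as the exact
mirror — the same rule applied to the reversed curve — which guarantees the
antisymmetry property that swapping the two conditions negates ΔTR, reverses
the ranking, and swaps the two classes exactly. A crossing absent from a tail
leaves that cutpoint (and its class) empty; a degenerate curve (all ΔTR
equal) has no defined cutpoints and raises.

Pause-release genes are those with ΔTR strictly above the value at `cut_hi`;
pause genes strictly below the value at `cut_lo`. Gene-set TR comparisons use
the two-sided two-sample KS test (exact null when n₁·n₂ ≤ 10⁴, asymptotic
otherwise) or Welch's *t*; both are exposed because the two are standard
alternatives for distribution-shift versus mean-shift questions, and the CLI
reports both.

## Single-cell track

QC keeps a cell iff it expresses ≥ `min_genes` genes (UMI > 0; default 200)
and its mitochondrial UMI fraction is ≤ `max_mito_fraction` (default 0.80) —
the thresholds define *exclusion* by strict inequality, so boundary cells are
kept, and the filter is idempotent. Mitochondrial genes are identified by a
case-insensitive `mt-` prefix unless an explicit mask is supplied.

Normalization is total-count scaling to `scale_total` (default 10⁴) with
optional log1p. The anchor covariance is the sample covariance (n−1
denominator) between each gene and the anchor across cells, per condition,
computed by default on *un-logged* normalized expression — a covariance
threshold with magnitude ~30 only makes sense on an un-logged scale — with
the scale recorded in the output metadata and a flag available for logged
input. The flag threshold (default 30) is a free parameter. The cell mask
(e.g. a luminal subset) is taken as input; how such a mask is derived
(clustering, marker thresholds) is outside this module's scope.

Census percentages are rounded to one decimal, matching how such counts are
conventionally printed. Pseudobulk/bulk concordance is the Pearson
correlation of log(UMI sum + 1) versus log(bulk count + 1) over genes
expressed (> 0) in both assays, with one-sided overlap counts reported.

## Stratification track

Signature scores: within each sample all N genes are ranked ascending by
expression (mean ranks on ties); with mean signature rank m over n_sig genes,
score = (m − (n_sig+1)/2) / ((2N − n_sig + 1)/2 − (n_sig+1)/2) ∈ [0, 1].
The score depends only on within-sample ranks, hence is invariant to any
monotone transform of a sample's expression vector. Signatures are treated
as up-regulated sets (no down-set handling); missing genes are dropped with
a warning, at least two must be present. The nine-gene AR activity panel
(KLK3, KLK2, FKBP5, STEAP1, STEAP2, PPAP2A, RAB3B, ACSL3, NKX3-1) ships as a
built-in constant.

Maxstat cutpoints: candidates are the distinct score values with empirical
quantile in (0.10, 0.90); for each, the cohort splits into score > c versus
≤ c and the standardized log-rank statistic (O−E)/√V with hypergeometric
variance is computed (vectorized over candidates); the cutpoint maximizes
|z|, ties toward the smaller value. No multiple-testing correction of the
max statistic is applied — the cutpoint is used only to form groups, and the
raw maximum is reported. "High" is *strictly* above the cutpoint, which
makes the candidate semantics ("split at value") unambiguous at ties.
A practical caveat verified in simulation: with two well-separated score
clusters the maxstat split reliably lands between the cluster centers, but
the argmax typically wanders one to a few samples into a cluster, so exact
sample-level partition recovery should not be expected of any
implementation of this statistic.

Kaplan–Meier estimation and the k-group log-rank test are delegated to
lifelines (product-limit convention: deaths before censorings at tied
times); the internal standardized log-rank used by maxstat is cross-checked
in the tests against lifelines and a hand hypergeometric computation. Cox
modelling, competing-risks regression and multiple-endpoint correction are
out of scope; group tables are exported for external tools.

## Synthetic-data generators

All generators are deterministic functions of config + seed, and their
outputs round-trip through the package's own readers (BED12, fragment BED,
bedGraph with an embedded library-size header, MTX + genes/barcodes/labels
TSVs, plain TSVs).

**Pol II track.** Genes are placed non-overlapping (sidestepping coverage
attribution for overlapping genes) with random strands and inter-gene gaps
on one synthetic chromosome; per gene and condition, the fragment count is
Poisson(reads mean, default 500), each fragment falls in the promoter with
the condition's pause probability and otherwise in the body, and is placed
uniformly *within* its region with fixed 200 bp length (configurable;
~200–500 bp is a typical sonication range, and constraining fragments to
their region makes the planted pause fraction exactly interpretable as a TR
allocation). Planted pause-release/pause gene sets shift the condition-2
pause fraction by −0.4/+0.4 by default.

Two defaults encode a deliberate benchmark design. Gene lengths default to
a narrow 1900–2100 bp band: TR scales linearly with body length, so length
heterogeneity both spreads the null ΔTR tails and compresses short planted
genes toward them; a narrow band isolates the pause-fraction effect the
benchmark plants. The baseline pause fraction defaults to 0.54, slightly
above one half — consistent with promoter-proximal signal dominating gene
body signal at most genes — which matters because the slope-1 tangent rule
couples the two tails through the shared y-range: the +0.4 pause tail then
spans large TR ratios, keeping the unit-square slope threshold above the
null tail's order-statistic spacing while the release tail still sustains
slope > 1. At a much higher baseline the release tail flattens below the
threshold; at 0.5 the null tail triggers early. Recovery at the benchmark
scale (3000 genes, 30+60 planted, 500 reads/gene) yields planted/recovered
Jaccard ≥ 0.8 per class across seeds.

**Single-cell track.** Each cell draws a latent activity a ~ N(0, 1); gene
g's mean count is base_g · exp(w_g·a), with the anchor loading (0.6) always
active and the covarying-set loadings (0.6) active in condition 1 only.
Counts are gamma-Poisson (negative binomial) with dispersion 10; Poisson is
recovered as dispersion → ∞. The transgene is Bernoulli(per-population
rate) × Poisson(mean 3) in condition 2 and absent in condition 1. The gene
universe is deep (default 1000 genes) with background base means uniform on
[1, 8] and a stronger anchor (base 8) / covarying set (base 4): on the 10⁴
normalization scale this puts the null covariance-difference noise several
standard errors below the default flag threshold of 30 while planted
covariance differences sit far above it (a design, not a fit: the budget
follows from var(count) = m + m²/φ and the 1/T² normalization factor).
A small panel of `mt-` genes is always included so QC paths are exercised.

**Survival track.** Each sample draws latent AR and MYC activities
~ N(0, 1); signature genes' log2 expression is shifted by 1.5 × activity
(a pure rank shift after the TPM column scaling), the quadrant group is the
sign pattern of the activities, and the event time is exponential with the
group's hazard (defaults 0.04/0.08/0.08/0.16, i.e. hazard ratio 4 between
the extreme quadrants), right-censored by an independent exponential
(rate 0.03).

### What the generators do and do not emulate

They reproduce the *statistical structure* the analyses consume — planted
promoter/body allocation shifts, condition-specific gene–anchor covariance,
hazard differences across signature quadrants — under idealized conditions:
no mappability or GC bias, no fragment-length variation, no overlapping
genes, no doublets or ambient RNA, no batch effects, single-chromosome
genomes, and narrow gene-length bands. Passing recovery tests therefore
demonstrates correctness of the computations and adequate power under the
planted effect sizes, not performance on real sequencing data, where
length heterogeneity and background signal will blur the ranked-curve knees
and covariance scales depend on sequencing depth.

## Problem sizes and numerical choices

The default test and demo sizes (3000-gene Pol II benchmarks, 2000 cells per
condition, cohorts of 200, demo track at 400 genes/400 cells/160 samples)
were chosen so the full suite and the acceptance script each run in well
under a minute on a single core while keeping planted effects comfortably
recoverable. Tolerances in tests follow the quantity's source: exact
equality for worked examples and identities, analytic grid tolerances
(±2 steps at 10⁴ points) for the knee oracle, 1e-10 for the log-rank hand
oracle, and interval bounds for Monte-Carlo rates. Degenerate inputs are
handled explicitly: empty regions, zero libraries, zero-total cells,
constant scores and all-equal ΔTR curves raise informative errors; short
genes and absent tangent crossings degrade to flags/empty classes rather
than exceptions.

## Known limitations

- The tangent cutpoint inherits the ranked curve's global min–max scaling:
  a single extreme ΔTR outlier rescales the whole curve and can move the
  knees; the smoothing window and persistence run damp but do not remove
  this.
- The covariance threshold is scale-dependent by design (un-logged,
  total-count-normalized expression); thresholds are not transferable
  across normalization choices, so outputs record the scale used.
- Maxstat p-values are not corrected for cutpoint selection; only group
  formation uses the cutpoint.
- BigWig output, isoform-level TSS handling, spike-in normalization,
  clustering/embedding, differential expression and Cox modelling are
  intentionally out of scope.
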