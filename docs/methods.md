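# Methods

This note documents the models, defaults and numerical choices behind
`clinexp`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Study design and data model

The pipeline targets a pooled-RNA-seq transect design: *P* populations
ordered by latitude, *C* replicate cages per population, and optionally
*T* repeated sampling times; one count library per (population, cage,
time). The two canonical configurations are the 18-sample common-garden
design (6 × 3 × 1) and the 72-sample in-situ design (6 × 3 × 4). All
statistics treat samples as independent points (replicate cages and
timepoints enter the correlations and fits directly); a
population-mean mode can be emulated by averaging columns first, but the
default mirrors the replicate-as-point convention used throughout the
analysis. Latitude stands in for the temperature gradient; on European
transects of this span the two are correlated at |r| > 0.99, so no
separate climate covariate is modelled.

## Normalization

Counts per million use raw library sizes (column sums). The
low-expression filter keeps transcripts with CPM ≥ `cpm_min` (default 2)
in at least `min_samples` samples; the replicate-group size (3, one
population's cages) is the default because group-wise filtering keeps a
transcript expressed in only one population testable.

TMM factors follow the canonical recipe: reference sample = the one
whose upper-quartile CPM is closest to the mean upper-quartile; per
sample, M = log2 ratio and A = mean log2 abundance over transcripts
nonzero in both sample and reference; rank-based double trim (30% per
tail on M, 5% on A); factor = 2 to the precision-weighted mean of the
trimmed M, with delta-method (binomial) weights; factors rescaled to
geometric mean 1. With the precision weights, scaling one library by a
constant changes the factors by ~1e-3 rather than 0 (only the weights
move, not the trimmed M values); exact invariance holds for pure global
depth changes. The implementation agrees with an independent
step-by-step reference to 1e-9 and, on development spot checks, with the
edgeR implementation to ~5e-9.

## Clinal screen

Per-transcript Pearson r against latitude with the two-sided t test on
n − 2 df; Spearman rho (midrank ties) computed alongside for the
method-concordance diagnostic. p-values are Benjamini–Hochberg adjusted
(step-up with monotonicity); direction = sign of r for transcripts with
q ≤ FDR (default 1%). Constant transcripts are reported `untestable`
and excluded from the adjustment rather than given r = 0, so they cannot
dilute the FDR. The Shapiro–Wilk normality screen is a diagnostic only —
its flags are reported, not used to drop transcripts, matching the
screen's reliance on the rank-based concordance as the robustness check.

## Cline-shape selection

Expression is min–max rescaled per transcript, x = (r − min r)/(max r −
min r), and latitude is re-expressed relative to the southernmost site.
Rescaling is invariant to positive affine transforms of the input, so it
does not matter whether raw or normalized counts are supplied as long as
normalization is a per-sample scaling. The error family is Gaussian with
profiled variance (σ² = RSS/n), which makes null/linear/step maximum
likelihood closed-form; the likelihood is the standard
logL = −(n/2)[log(2πσ²) + 1]. A configurable σ floor of 1e-6 (rescaled
units) keeps perfect fits finite; below the floor the exact Gaussian
log-likelihood at σ = floor is used.

Parameterizations and parameter counts (including σ):

| model | mean function | k |
|---|---|---|
| null | x_s | 2 |
| linear | x_s + b·l | 3 |
| step | x_s + d·1{l ≥ l_c} | 4 |
| sigmoid | x_s + (d/2)(1 + tanh(κ(l − c))) | 5 |

The sigmoid's reported slope statistic is s = d·κ/2, the slope at the
centre (its maximum). The step position l_c is profiled exactly over the
P − 1 midpoints between consecutive distinct latitudes: with discrete
sites it is identified only to an interval and the midpoint is the
canonical representative. The sigmoid is fitted by bounded
trust-region least squares (x_s ∈ [−3, 3], d ∈ [−3, 3], κ ∈ [0.01, 50]
per degree, c within the sampled range) started from the best point of a
25 × 25 (κ log-spaced × c linear) grid at which (x_s, d) are solved in
closed form and clipped into the box — so every start is feasible and
its RSS matches its parameters.

Selection is minimum AIC = 2k − 2 logL, with ties (ΔAIC < 1e-6) broken
toward fewer parameters in the order null < linear < step < sigmoid.
Constant transcripts skip fitting and are assigned null directly.
The test suite verifies the selected optimum against an independent
dense-grid search with Nelder–Mead polish of the 2-D profiled objective
(agreement within ΔAIC ≤ 1e-3 on random instances).

**Known statistical limitation.** Minimum-AIC selection over nested
models overfits at a fixed, irreducible rate: a richer model wins when
its likelihood-ratio gain exceeds twice the extra parameter count, which
for two extra parameters happens with probability ≈ e⁻² ≈ 13.5% under
the null of the simpler model. On planted data (σ = 0.02, |d| ∈
[0.6, 1]) this yields ≈ 73% correct selection for true-null transcripts
(losses to step and linear) and ≈ 86% for true-linear (losses to
sigmoid), while true step/sigmoid transcripts land in the {step,
sigmoid} family essentially always. Restricting shape fitting to
CE-screened transcripts (the default) removes most true nulls before
fitting; users who need conservative shape calls should additionally
require a ΔAIC margin rather than the bare minimum.

## Enrichment, τ and rank tests

Representation of a gene set among +CE (or −CE) transcripts uses the
2×2 table (in class vs not) × (in set vs not) over the universe of
testable transcripts, chi-square with Yates continuity correction
(the uncorrected statistic is reported alongside), and margin-adjusted
standardized residuals (O − E)/√(E(1 − row/N)(1 − col/N)), whose null
distribution is standard normal — the variant consistent with
double-digit residuals on large tables. Expected-zero cells raise an
error directing to the Fisher exact test, which is also provided for set
overlaps (two-sided, sample odds ratio).

τ = Σᵢ(1 − xᵢ/max x)/(N − 1) over N tissues: 0 for uniform, 1 for
single-tissue expression; values above ~0.9 indicate tissue-specific
genes. All-zero profiles are undefined (NaN). Testis bias is testis
expression ≥ 50× the highest other tissue; 256× (2⁸) is the stricter
variant appropriate for dedicated testis-expression datasets. The
+CE/−CE τ comparison uses the Wilcoxon–Mann–Whitney test with W the
rank-sum statistic of the first group (R's `wilcox.test` convention),
exact for small tie-free samples and normal-approximated with tie
correction otherwise (scipy's switching rule).

## mtDNA confound check

Focal-allele frequency = count_A/depth per sample; samples with depth
< 10 are discarded (and listed) before the Pearson correlation of
frequency with latitude. Constant frequencies are untestable and
reported as consistent with "no cline", which is the outcome that rules
out the confound. The verdict threshold is an unadjusted p = 0.05 on a
single test; as the worked example shows, a no-cline truth still
triggers a false alarm at the expected ~5% rate, so the verdict string
is a summary, not an inference procedure.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions under
which the pipeline is validated:

- **Design**: 6 populations at (39.5, 43.8, 47.5, 51.2, 55.5, 59.8)° N —
  an approximate Valencia→Uppsala transect, configurable — 3 cages,
  1 or 4 timepoints.
- **Counts**: negative binomial with mean = (library size/10⁶) ×
  baseline × response(latitude). Baselines are log-normal on the CPM
  scale (log-mean log 30, log-sd 1.2: a realistic abundance span of
  ~1–10³ CPM); library sizes log-normal around 2 × 10⁶ reads (log-sd
  0.15); dispersions gamma-distributed with mean 0.05 (shape 2), typical
  of pooled-sample RNA-seq. Both distributions can be switched off to
  scalar values for tests.
- **Cline shapes**: the response is multiplicative relative to the
  southernmost site — 1 at the south, 1 + d (signed) at the north —
  with the same linear/tanh/step parameterizations as the fitting
  module; shape mixture defaults to 85% null / 9% linear / 3% sigmoid /
  3% step (most transcripts are not clinal; linear is the commonest
  clinal form), |d| ∈ [0.3, 1]. Sigmoid steepness κ ∈ [0.5, 2] per
  degree and centre in the middle 40% of the transect keep planted
  sigmoids distinguishable from both linear and step at 6 sites.
- **Annotations**: metabolic membership at base rate 0.15, odds ×3 among
  positive clinal transcripts; testis bias at base rate 0.10, odds ×3
  among negative clinal transcripts; a neutral circadian set (5%) as a
  negative control. Testis-biased transcripts get profiles of 800–1500
  in the testis against 1–8 elsewhere (fold ≫ 50, τ ≈ 1); all others
  near-uniform profiles (τ ≈ 0.3).
- **mtDNA**: binomial allele counts at Poisson-distributed depths
  (mean 60), equal true frequency 0.8 across populations by default (no
  cline); low-depth samples can be forced to exercise the filter.
- A cage-level log-normal random effect is available but defaults to
  zero: the variance decomposition between cages within populations is
  not identified by the motivating design, so none is imposed.
- Determinism: every draw flows from `numpy.random.default_rng` seeded
  by (seed, stage salt); identical configs are bit-identical.

What the generator does **not** emulate: transcript-to-transcript
count correlation (co-expression), GC/length biases, batch effects
between sequencing runs, seasonal structure in the 4-timepoint mode
(timepoints are exchangeable replicates), and cross-species homology
noise in the annotation tables. Passing recovery tests therefore show
the statistics do what they claim under the stated sampling model, not
that real-data clines of a given size will be recovered at the same
rates.

## Problem sizes used in validation

The recovery experiments run at 500 planted transcripts per shape
(2000 total) for shape selection, 10⁴ transcripts × 20–50 replicates for
the null false-call rate, 2000 transcripts for screen power, and 10–20
seeded replicates for enrichment recovery — sizes at which the
Monte-Carlo error on the reported rates is well below the margins being
tested, while a full run of the acceptance script stays under a minute.
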