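# Methods

This note documents the statistical model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## The experimental design being modelled

A factorial DIA-MS experiment: two tolerance classes (each represented by
two genotypes), two sampling days (baseline day 0 and stress day 6), three
biological replicates per genotype per day — 24 samples. Day is a factor,
not a continuous covariate: with two time points nothing smoother is
identifiable. The analysis treats genotypes within a class as biological
replicates by default (`model="class_day"`, 6 samples per class-day cell);
a genotype-level model (`genotype_day`) is available and aggregates
genotype cell means to class level in the contrasts, which on a balanced
design yields identical class-level effect estimates.

## Preprocessing

* **Scale.** All analysis is on log2 intensities. Raw matrices are
  transformed once and flagged; zeros in raw exports are treated as
  non-detections by default because DIA search engines use 0 to encode
  "not quantified", and detection counting must not mistake 0 for an
  observation (flag to disable).
* **Normalization.** The upstream method is not prescribed, so the default
  is per-sample median centering to the median of sample medians — robust,
  standard for DIA matrices, and it equalizes observed sample medians
  exactly. A rank-based quantile mode is available behind a flag; neither
  is claimed to be "the" original method.
* **Missingness filter.** Proteins missing in strictly more than 75% of
  all samples are removed; a protein at exactly 75% is retained. The
  denominator is all samples, not per-group, because the filter precedes
  any group analysis. The filter is idempotent and monotone in its
  threshold (tested).
* **Imputation.** "Minimal-value" imputation with three selectable
  variants: `global_min` (default; every missing cell takes the minimum
  observed value of the matrix), `per_protein_min`, and `downshift(k)`
  (global minimum − k, default 1 log2 unit). Observed cells are never
  altered, and the pre-imputation mask is carried alongside the imputed
  matrix because every detection-based analysis must use the original
  mask. The choice of variant is logged; the default is the most
  conservative w.r.t. creating spurious intensity differences, at the cost
  of inflating within-group variance for heavily censored proteins.
* **QC.** Missing fractions (per sample and per class-day group) come from
  the original mask; Pearson correlations use pairwise-complete
  observations; the variance decomposition eigen-decomposes the sample
  covariance (SVD of the protein-centered matrix) and reports, for each of
  the two leading axes, the between-group variance fraction (eta-squared
  of the axis scores) under the day grouping and under the class grouping.

## Moderated differential abundance

Per protein, ordinary least squares against the dummy-coded factorial
design (intercept, class, day, class:day; residual df d = n − rank = 20
for the full design). Residual variances are shrunk by placing a scaled
inverse chi-square prior on the true variances, under which s²/s₀² follows
an F(d, d₀) distribution. With e = log s² − ψ(d/2) + log(d/2):

* Var(e) − ψ′(d/2) = ψ′(d₀/2) gives d₀ by Newton inversion of the trigamma
  function;
* mean(e) = log s₀² − ψ(d₀/2) + log(d₀/2) gives s₀² in closed form.

This is the classical moment-matching-on-log-variances estimator; the test
suite cross-checks it against R/limma's `eBayes` on a shared fixture and
the two agree to ~1e-13 on t-statistics, p-values, d₀ and s₀². The
posterior variance is s̃² = (d₀s₀² + ds²)/(d₀ + d), always between s² and
s₀²; the moderated t uses s̃² and is referred to a t distribution with
d₀ + d degrees of freedom. Two-sided tests throughout.

Numerical edges:

* **Zero residual variance** (possible when minimal-value imputation makes
  a group constant) is floored at machine epsilon and flagged
  (`var_floored`) before moderation, so log s² stays finite.
* **All variances identical** is a degenerate input for the moment
  estimator (its model ascribes chi-square spread to sampling noise, so the
  raw formulas would return s₀² ≠ the common value); it is special-cased to
  d₀ = ∞ with s₀² equal to the common value, the natural fixed point.
* **Fewer than 10 usable variances** disables moderation (d₀ = 0) with a
  warning rather than estimating a prior from almost nothing.
* d₀ = 0 reduces exactly to the classical t; d₀ = ∞ replaces every s² by
  s₀². Both limits are tested.

Contrasts are coefficient vectors assembled from design rows of cell
means, so the same code path serves the baseline class difference
(tolerant − sensitive at day 0), the within-class day responses, and the
interaction ((tolerant day6 − day0) − (sensitive day6 − day0)); the
interaction coefficients sum to zero by construction. Benjamini–Hochberg
adjustment is a hand-implemented step-up with monotone enforcement; NaN
p-values propagate and are excluded from m. DAP calling requires
adjusted p < 0.05 **and** |log2FC| ≥ 1 (boundary significant); the
interaction call uses only FDR < 0.05 because no fold-change gate is
prescribed for it — whether one should apply is genuinely open, and we
chose the permissive reading and surfaced the flag.

## Detection-based classification

All detection analyses read the pre-imputation mask. The reliability rule
for an intensity-driven DAP is detection in ≥ 2/3 replicates per genotype
(or ≥ 4/6 in a pooled class cell) in **both** conditions of the contrast.
Proteins failing reliability are detection-driven candidates when the
pooled detection-proportion gap between the two conditions is
≥ `freq_delta_min` = 0.5; otherwise `none`. The 0.5 default, and the
switch-like thresholds below, are declared package defaults (configurable
and logged), not reconstructions of the original cutoffs, which were not
numeric; 2/3 mirrors the reliability convention.

* **On/off**: detected in all replicates of one class at both days and at
  most `off_max` = 0 in the other class at both days.
* **Switch-like**: one class high at baseline (proportion ≥ 2/3) and low
  at the stress day (≤ 1/3) with the other class inverted; both
  orientations are searched and reported.

These are deterministic functions of the mask; on noiseless planted
patterns recovery is exact (sensitivity = specificity = 1, tested). Under
30% MNAR censoring, unplanted low-abundance proteins can genuinely satisfy
the rules — those are correct detections of chance patterns, not false
positives of the classifier, which is why the exactness guarantee is
stated for the noiseless regime.

## Enrichment

One-sided (over-representation) hypergeometric tests, upper tail
P(X ≥ k) with X ~ Hypergeom(N, K, n), via `scipy.stats.hypergeom` and
verified against full combinatorial enumeration to 1e-12. The background
is the quantified protein set, and both the background and the DAP set are
intersected with the annotated universe first — proteins without any
annotation contribute to neither n nor N; dropped counts are logged.
Pathways with fewer than `min_size` = 3 background members are skipped.
BH is applied within one run (one directional DAP set × one annotation
collection), mirroring per-set reporting. Fold enrichment is
(k/n)/(K/N).

## Microclimate and physiology

SVP(T) = 0.61078·exp(17.27·T/(273.5 + T)) kPa. The 273.5 denominator
reproduces the upstream convention verbatim even though the classical
Tetens/Magnus constant is 237.3 — at 25 °C the difference is ~18% of SVP,
which is material, so the discrepancy is surfaced as an explicit
`denom_const` parameter (CLI `--tetens`) rather than silently corrected.
VPD = SVP·(1 − RH/100); identities (VPD = 0 at RH 100, monotone increasing
in T, decreasing in RH) are tested on grids. Stress-window summaries use
the half-open window [10:00, 16:00) (inclusive-end flag available),
averaging within treatment-day first so partially logged days are not
over-weighted.

Trait tables (chlorophyll, POD, MDA) are analysed by two-way
fixed-effects ANOVA (class × day) with Type-II sums of squares —
unambiguous for main effects when unbalanced and identical to the
classical decomposition when balanced (the balanced SS identity is
tested) — followed by Tukey HSD over the class-day cell means, both via
statsmodels. An all-constant response is reported as degenerate with a
warning instead of dividing by zero.

## Synthetic data: what it emulates, what it does not

True log2 intensities are additive — protein baseline ~ N(20, 2²), planted
effects, residual noise N(0, 0.5²) — matching the additive-on-log2 model
the differential machinery assumes. Defaults plant 200 day effects, 100
class effects and 50 interaction effects at |log2FC| = 2, plus 10 on/off
and 10 switch-like detection patterns, in mutually exclusive protein
blocks recorded in a truth registry. Missingness is logistic
left-censoring on the true intensity, P(missing|x) = 1/(1 + e^{s(x−m)}),
with the midpoint m calibrated by bisection at generation time so the
realised overall rate hits `missing_target` = 0.30 in expectation
(empirically within ±0.01 at 5,000 proteins). Setting the steepness to 0
selects pure MCAR with per-cell probability equal to the target (the raw
logistic would degenerate to 0.5 and ignore the target); whether real DIA
missingness is purely MNAR is unknowable from the summary statistics the
generator is built to match, so both mechanisms are exposed. Planted
detection patterns bypass stochastic censoring so their masks are exact in
the default noiseless mode; a noise parameter can flip replicates for
robustness exercises.

Deliberately not emulated: peptide/spectrum-level structure, retention
time, m/z, batch effects, correlated proteins (rows are independent given
the design), and heavy-tailed intensity noise. A green recovery test
therefore establishes that the statistics do what they claim under the
assumed additive-Gaussian MNAR world — not that the pipeline is robust to
violations of that world.

The microclimate generator produces paired 30-min logger series with a
sinusoidal diurnal cycle (amplitude 6 °C, peak 14:00) around a control
mean of 30 °C, an enclosure offset of +4.9 °C (the magnitude of enclosure
heating in the motivating field setup), constant-by-default RH, and
Gaussian logger noise. The trait generator plants a higher-chlorophyll
tolerant class, a chlorophyll decline with exposure time, and POD/MDA
increases with time — the qualitative structure such assays show — with
5% multiplicative noise.

## Reproducibility

Every stochastic component takes a single integer seed through
`numpy.random.default_rng`; the pipeline writes no timestamps into
analysis tables, so a fixed configuration reproduces byte-identical DAP,
pattern and enrichment tables (tested end-to-end). The run manifest
records the config snapshot, per-stage record counts, thresholds, seed and
software version.

## Known limitations

* Minimal-value imputation biases fold changes toward the detection limit
  for heavily censored proteins; the dual-track design mitigates but does
  not remove this (a censored-likelihood model is out of scope).
* The moderated model assumes a common residual df across proteins (true
  after imputation, which completes the matrix).
* Detection thresholds (0.5 frequency gap, 2/3–1/3 switch bounds) are
  conventions, and results near those boundaries should be read as such.
* With only two days, "switch-like" means a single crossover between two
  snapshots; no claim about trajectory shape is possible.
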