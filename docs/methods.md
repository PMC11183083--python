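# Methods

This note documents the statistical model behind `batcheval`, the estimator
conventions it commits to, the numerical choices that matter, and what the
synthetic-data generator does and does not emulate.

## The problem

A radiomics feature matrix is an n × m table of real-valued image features.
When samples come from several scanners, sites, or acquisition years, the
per-feature distributions can differ across those "batches" in location and
scale even when the underlying biology is exchangeable.  The package
answers two questions: *is there a batch effect in this dataset at all*
(screening, one decision for the whole matrix), and *how large is the
effect in each feature* (quantification, one effect size per feature per
batch level) — plus the standard follow-up, *did harmonization remove it*.

## Simulation model

The generator draws i.i.d. residuals ε ~ N(0, 1) per (sample, feature),
assigns each sample uniformly at random to one of two batches (unbalanced
draws are kept; an assignment leaving any batch with fewer than two samples
is redrawn a bounded number of times), and, in the batch-effect arm,
applies per-batch scale then location:

    y = γ_batch + δ_batch · ε,    δ ~ U(0.8, 1.2),  γ ~ U(−2, 2).

Defaults are 20 features per dataset and sample sizes 100 / 1000 / 2500
with 250 iterations per condition — the operating points of the power
study.  Two conventions deserve comment:

* **Parameter sharing.**  By default one (γ, δ) pair is drawn per batch per
  dataset and applied to *every* feature.  This is the consequential
  choice: with shared draws, an iteration whose two batch locations happen
  to nearly tie produces a dataset in which *no* feature carries a usable
  signal, which is what keeps dataset-level power strictly below 1 at
  n = 100 (Clark-distance power ≈ 0.95 rather than ≈ 1).  Independent
  per-(batch, feature) draws are available via `params_per_feature=True`;
  per-feature marginal distributions are identical under the two schemes,
  but Monte-Carlo variances of study-level summaries are not.
* **No-batch arm.**  Implemented by omitting γ and δ entirely, which is
  algebraically the same as γ = 0, δ = 1.

Reproducibility: iteration k of a study uses the RNG substream
`SeedSequence(base_seed, spawn_key=(k,))`, so any iteration can be
regenerated in isolation and iterations are independent by construction.

What the generator does **not** emulate: real radiomic features are
correlated within feature families, non-Gaussian, and may confound batch
with biology; batch effects can also live in the covariance structure or in
several crossed batch variables.  Passing the simulation study therefore
demonstrates correct operating characteristics under location/scale effects
on independent Gaussian features — not performance on any particular real
dataset.

## PERMANOVA

The pseudo-F statistic is computed two mathematically equivalent ways:

* the trace form F = [tr(HGH)/(g−1)] / [tr((I−H)G(I−H))/(n−g)], with
  G = C(−½D∘²)C, C = I − 11ᵀ/n, and H the block hat matrix
  (H_ij = 1/n_k when i and j share batch k);
* the sum-of-squares identity SS_T = (1/n)Σ_{i<j}d²_ij,
  SS_W = Σ_k (1/n_k)Σ_{i<j∈k}d²_ij, SS_B = SS_T − SS_W.

The second costs O(n²) per permutation with no matrix products and is used
in the permutation loop (indicator-matrix products over permutation blocks,
so a 2000-permutation test at n = 2500 stays in BLAS); the trace form is
kept and cross-checked in the tests.  The permutation null permutes labels
uniformly (group sizes preserved), and p = (1 + #{F_perm ≥ F_obs}) /
(1 + B): never exactly zero, matching the usual Monte-Carlo convention.
Ties in F against F_obs use plain ≥ with no tolerance; F is continuous so
exact ties have measure zero.  If every within-batch distance is zero, F is
reported as +∞ with a warning rather than an error.

Distance conventions follow the vegan `vegdist` definitions (verified
against it on fixtures): Clark includes the 1/M′ normalization over
informative columns (a switch disables it, since published definitions
differ by this constant); Gower drops zero-range columns from its average
rather than treating them as distance 0; Jaccard is 2B/(1+B) of Bray–Curtis
B; Mahalanobis uses the unregularized sample covariance and raises an
explicit singular-covariance error when the smallest eigenvalue is
non-positive or below 1e−10 of the largest — deliberately mirroring the
failure mode this metric exhibits on collinear feature sets (an optional
explicit covariance can be injected instead).

The exponential transform e^x is applied, by default, only where a metric's
domain requires positivity (Clark, Jaccard); `transform="all"` and
`"none"` cover the alternative readings.  The transform is monotone, so
rank-based univariate tests are exactly invariant to it; for the distance
metrics it magnifies large values and hence tends to amplify location
differences, which is consistent with Clark and Jaccard being the most
powerful metrics in the study.

## RESI

Per feature, an OLS fit of the feature on the reference-coded batch factor
(closed-form group statistics; validated against statsmodels) with an HC3
sandwich covariance by default (HC0–HC3 selectable).  Conversions to the
effect-size scale:

* per non-reference coefficient: **S = z/√n**, signed, where z is the
  robust Wald z-statistic — the standard single-parameter conversion; for a
  balanced two-group mean difference S → d/2;
* joint batch effect: **S = √(max{0, (χ² − df)/n})** for the robust Wald
  χ² over the g−1 coefficients; the truncation at zero is part of the
  estimator.

The two conventions coincide asymptotically; at g = 2 they differ by the
df correction (overall² = max{0, S² − 1/n}).  The per-coefficient z/√n
form is what the reference implementation reports for individual
coefficients and is the scale on which the simulation's null summaries
(mean |S| ≈ 0.8/√n) and bootstrap interval widths (≈ 3.9/√n) arise; a
`df_adjust` switch provides the truncated per-coefficient variant
sign(z)·√(max{0,(z²−1)/n}) for users who want the df-corrected form
everywhere.  The intercept never receives an effect size: the reference
value β₀ is zero for batch coefficients.

Confidence intervals are nonparametric case-resampling percentile
bootstrap intervals (500 replicates by default) of the signed
per-coefficient S and of the overall S.  Replicates that lose a batch
level entirely are redrawn (bounded rounds).  The bootstrap is vectorized
as per-group count/sum/sum-of-squares aggregations, so 500 replicates cost
a few matrix operations rather than 500 regression fits.  Percentile
intervals were chosen over BCa for simplicity and because coverage of the
long-run mean estimate at the study's operating points is the only
calibration surface; empirical coverage in the tests sits at ≈ 95%.

Degenerate inputs: a feature constant within every batch has zero residual
variance and no defined robust variance; per-feature processing records
such features with a reason code instead of failing the whole table.

## Univariate comparators

Wilcoxon rank-sum (tie-corrected normal approximation), two-sample
Kolmogorov–Smirnov (asymptotic p), and the Scholz–Stephens k-sample
Anderson–Darling test (midrank version), all via scipy.  WRS and KS are
restricted to two batch levels and are reported as "unsupported" rows — not
errors — on many-level designs, where only the AD test applies.  AD
p-values come from the published interpolation of the asymptotic null,
which is tabulated for tail probabilities in [0.001, 0.25]; p-values are
clamped to that range, so 0.001 is the documented floor replacing "p = 0"
for extreme statistics and 0.25 means "no evidence against the null".
Feature-level power is the fraction of rejecting (iteration, feature) tests
pooled across iterations; the per-iteration mean rejection fraction is also
reported, and Monte-Carlo SEs are computed on the iteration scale because
features within an iteration share batch parameters.

## ComBat

Standard parametric empirical-Bayes location/scale harmonization: fit
batch + covariate OLS per feature, standardize by the batch-size-weighted
grand mean and pooled residual SD (divisor n), estimate per-batch
location/scale on the standardized scale, shrink across features with a
normal prior on locations and an inverse-gamma prior on squared scales
(moment-matched hyperparameters), iterating the conditional posterior-mean
equations to a relative tolerance of 1e−6 (cap 100 iterations).  Covariate
effects are added back untouched ("protected").  Agreement with the
Bioconductor reference implementation is checked in the test suite to
1e−4.  Special cases: a single batch level returns the identity transform
(the across-feature moment priors are undefined there); constant features
bypass adjustment with a warning; a covariate exactly confounded with
batch is a rank-deficiency error.  Non-parametric priors and
reference-batch mode are out of scope.

## Power study and problem sizes

`run_power_study` simulates each (arm, sample size) condition with
per-iteration substreams, producing dataset-level PERMANOVA decisions per
metric, feature-level univariate decisions per test, and RESI summaries,
with binomial/empirical Monte-Carlo SEs throughout.  A `scale` factor
divides iteration, permutation, and bootstrap counts uniformly for quick
runs; because SEs are always carried, scaled runs remain interpretable.

The shipped acceptance script uses 250 iterations × 1000 permutations at
n = 100, 80 × 400 at n = 1000, and 30 × 250 at n = 2500 (where per-dataset
signal is so strong that power is saturated and extra replicates buy
little), 250 and 120 iterations for the feature-level AD power at n = 100
and 2500, and 400 iterations × 600 permutations for the null-arm
calibration, whose summary is the mean rejection rate over the nine
implemented methods (six PERMANOVA metrics, three univariate tests).

## Known limitations

* The simulator covers location/scale effects on independent Gaussian
  features only; covariance-structure effects, multiple batch variables,
  and batch–biology confounding are out of scope.
* PERMANOVA is implemented for a single categorical factor (no covariate
  adjustment or sequential sums of squares), which is the screening use
  case.
* RESI is implemented for the linear batch model only, not the wider
  family of models the index generalizes to.
* AD p-values are interval-censored at [0.001, 0.25] by the published
  interpolation table; decisions at α = 0.05 are unaffected.
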