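# batcheval

Batch-effect evaluation for radiomics-style feature matrices.

Multi-center imaging studies produce sample × feature tables in which
technical factors — scanner, site, acquisition year — leave "batch effects":
shifts in the location and scale of feature distributions that have nothing
to do with biology but degrade reproducibility and downstream models.
`batcheval` implements a two-level evaluation workflow for such tables:

* **Dataset-level screening with PERMANOVA.**  Given an n × n distance
  matrix *D* over samples and a g-level batch variable, the pseudo-F
  statistic

  $$F \;=\; \frac{\operatorname{tr}(HGH)/(g-1)}{\operatorname{tr}\!\big[(I-H)G(I-H)\big]/(n-g)}$$

  compares between- to within-batch dissimilarity, where *G* is Gower's
  double-centering of $A = -\tfrac12 D^{\circ 2}$ and *H* the hat matrix of
  the one-hot batch design.  Significance comes from uniform random
  relabelings (2 000 permutations by default, add-one p-value).  Six
  distance metrics are supported — Euclidean, chord, Clark, Gower,
  Jaccard (a monotone transform of Bray–Curtis), Mahalanobis — with an
  elementwise exponential transform supplying the strictly positive domain
  that Clark and Jaccard require.

* **Feature-level effect sizes with the Robust Effect Size Index (RESI).**
  Each feature is regressed on the batch factor; with a
  heteroskedasticity-consistent (HC3) covariance $\Sigma_\beta$, the signed
  per-coefficient index is $S = z/\sqrt{n}$ and the joint index is
  $S = \sqrt{\max\{0,\,(\chi^2 - \mathrm{df})/n\}}$ for the robust Wald
  statistic $\chi^2=\hat\beta^{\top}\Sigma_\beta^{-1}\hat\beta$ over the
  non-reference batch coefficients.  *S* is unitless (≈ Cohen's d / 2 for a
  balanced two-group shift) and stays interpretable at sample sizes where
  p-values saturate at 0.  Uncertainty comes from a 500-replicate
  case-resampling bootstrap (percentile intervals).

* **Univariate comparators** — Wilcoxon rank-sum, two-sample
  Kolmogorov–Smirnov, and the Scholz–Stephens k-sample Anderson–Darling
  test — applied feature-wise, as the baseline these multivariate tools are
  evaluated against.

* **ComBat harmonization** (parametric empirical-Bayes location/scale
  correction with covariate protection) to produce the "after" arm of a
  pre/post comparison.

* **A simulation harness** reproducing the power / Type-I-error experiment:
  datasets of 20 features for n ∈ {100, 1000, 2500}, two random batch
  groups, per-batch scale effects δ ~ U(0.8, 1.2) applied to standard-normal
  residuals and location effects γ ~ U(−2, 2) added on top.

## Worked example

Simulate a 200-sample, 20-feature dataset with batch effects (this seed
draws batch locations γ ≈ 1.93 and −1.78, a strong effect), then screen,
quantify, and harmonize:

```sh
batcheval simulate --n-samples 200 --seed 1 --out-prefix demo
batcheval screen demo_features.csv demo_metadata.csv --batch-col batch \
    --permutations 2000 --seed 4 --out demo_screen.json
```

```
euclidean: pseudo-F=611.9897 p=0.0004998
chord: pseudo-F=621.3818 p=0.0004998
clark: pseudo-F=180.0247 p=0.0004998
gower: pseudo-F=850.2052 p=0.0004998
jaccard: pseudo-F=90.1275 p=0.0004998
mahalanobis: pseudo-F=10.2892 p=0.0004998
```

Every metric rejects at the smallest attainable p-value,
1/(2000+1) ≈ 0.0005: the batch split explains far more of the pairwise
dissimilarity than random relabelings do.  Now compare the data with its
ComBat-harmonized version:

```sh
batcheval compare demo_features.csv demo_metadata.csv --batch-col batch \
    --permutations 499 --boot 200 --seed 4 --out-prefix demo_cmp
```

```
{
  "mean_abs_resi_pre": 1.7497407460811387,
  "mean_abs_resi_post": 0.04002779438707791,
  "ad_rejection_pre": 1.0,
  "ad_rejection_post": 0.0,
  "permanova_p_pre":  { "euclidean": 0.002, ... "mahalanobis": 0.002 },
  "permanova_p_post": { "euclidean": 0.988, ... "mahalanobis": 0.994 }
}
```

Before harmonization the mean |RESI| across features is 1.75 (a batch shift
of ≈ 3.5 residual standard deviations, consistent with S ≈ d/2) and every
Anderson–Darling test rejects; after ComBat the mean |RESI| collapses to
0.04 — the null floor — and no test rejects.  The effect size, unlike the
p-values, says *how much* batch signal was present and how much remains.

The same operations are available as library calls (`screen_dataset`,
`quantify_dataset`, `compare_harmonization`, `run_power_study`, ...) on
`FeatureMatrix`/`BatchLabels` objects; `read_dataset` loads any delimited
feature + metadata table pair.

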