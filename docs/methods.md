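# Methods

This note documents the statistical procedures implemented in `respsig`, the
defaults and the reasoning behind the genuinely open design choices. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Composite constructs

Each power domain is summarized by a single baseline-anchored construct.
Let `x_ij^t` be swimmer *i*'s raw value on indicator *j* at time *t*, and
`μ_j, σ_j` the Pre-sample mean and SD (n−1 denominator). A one-component PCA
is fitted to the correlation matrix of the standardized Pre block; the
leading eigenvector **w** (unit norm) is the fixed loading vector and
`variance_explained` is the leading eigenvalue over the trace. Scores at
every time point use the *baseline* constants:

    score_i^t = Σ_j w_j (x_ij^t − μ_j) / σ_j

Design choices:

* **Correlation-matrix PCA.** Fitting on the correlation (not covariance)
  scale makes the construct invariant to the arbitrary units of the raw
  indicators; for a two-indicator domain it forces the symmetric loadings
  (0.707, 0.707) and `variance_explained = (1 + r)/2` exactly.
* **Sign convention.** The leading eigenvector is oriented so its
  coefficient sum is positive (all power indicators point the same way);
  a zero sum is disambiguated by making the first coefficient non-negative.
* **Raw projection.** Scores are not rescaled by the eigenvalue, so a change
  of +1 on one indicator's baseline-SD scale moves the composite by that
  indicator's loading. Composite changes are reported in these "composite
  units". Rescaling to unit baseline variance would be an equally defensible
  convention; the raw projection was chosen because it keeps the loading
  weights interpretable and is assumed by the synthetic generator's
  calibration (below).
* **Missing data are rejected, not imputed** — the pipeline analyzes
  completers only.

Degenerate inputs (an indicator with zero baseline variance, fewer than
three athletes) raise typed errors naming the offending input.

## Synthetic cohort generator

The generator provides seeded cohorts whose analysis output matches the
structure the pipeline targets. Per swimmer it draws a latent Pre score per
domain ~ N(0, 1) and a composite-scale change per domain
~ N(μ_g, σ_g) for the swimmer's arm; the Mid latent is the Pre value plus
`mid_fraction` (default 0.5) of the change. Each of the domain's *m*
indicators equals the latent plus a *stable* swimmer-specific offset
~ N(0, σ_noise), constant across time points, then an affine map to a
plausible raw scale (bench press ≈ 300 ± 60 W, CMJ ≈ 35 ± 5 cm, …; these
constants cancel in the analysis).

Two calibrations make the full pipeline recover the configured quantities:

* **Latent-change scale.** The composite projection multiplies a common
  latent change by `√m / √(1 + σ_noise²)` (equal loadings, baseline SD
  `√(1 + σ_noise²)`). The generator therefore injects
  `δ = c · √(1 + σ_noise²)/√m` for a target composite change *c*, so the
  group-wise mean *and* SD of the recovered Δ composites converge to
  (μ_g, σ_g) as n grows. Time-varying indicator noise is deliberately
  excluded from the default model: independent per-time-point noise inflates
  the variance of change scores (Var(Δ) picks up `2σ²/(1+σ²)`), which would
  contradict the small per-group change SDs the generator is meant to
  emulate. The stable offset instead represents persistent
  technique/anthropometry differences in how a swimmer expresses the latent
  construct on each test.
* **Noise SD.** The baseline correlation between two same-domain indicators
  is `1/(1 + σ_noise²)`. Defaults are calibrated per domain to r = 0.913
  (upper; PC1 fraction 0.957) and equicorrelation 0.932 (lower; PC1
  fraction (1 + 3r)/4 = 0.949).

Default change parameters (composite units) per arm:

| arm  | ΔUpper μ (σ) | ΔLower μ (σ) |
|------|--------------|--------------|
| MSTG | 0.962 (0.129) | 0.822 (0.125) |
| PTG  | 0.762 (0.218) | 0.758 (0.150) |
| CG   | 0.332 (0.058) | 0.388 (0.059) |

Covariates (sex counts, age, training years, best 50 m time) follow the
per-arm summaries of the emulated cohort. Upper- and lower-domain changes
are drawn independently by default; `delta_corr` induces a within-swimmer
correlation for clustering experiments. What the generator does **not**
emulate: sex effects on the indicators (none are injected), in-water
outcomes, measurement drift across waves, and dropout — so passing tests
demonstrate correctness of the pipeline's machinery under the stated
generative model, not robustness to those real-data features.

## Group contrasts

Per endpoint (ΔUpper, ΔLower) and group pair:

* **Descriptives:** mean, sample SD, and t-based 95% CI
  (`mean ± t_{0.975, n−1}·sd/√n`). The t multiplier (not 1.96) is the
  convention that reproduces standard small-sample reporting.
* **Permutation test:** two-sided, statistic = difference in means,
  relabelings preserve group sizes. Monte Carlo p uses the
  `(1 + #{|T*| ≥ |T|})/(n_perm + 1)` estimator (guarantees p > 0; an
  uncorrected variant is available via `plus_one=False`). Pooled samples of
  ≤ 12 are enumerated exhaustively instead. Ties are counted with a 1e-12
  relative tolerance.
* **Bootstrap CI:** percentile interval from 20,000 stratified resamples
  (within-group, preserving the two-sample design).
* **Hedges g:** pooled-SD standardized mean difference times
  `J = 1 − 3/(4·df − 1)`, df = n_a + n_b − 2.
* **Holm adjustment** across the three pairwise contrasts within each
  endpoint (family size 3).

Rendered tables round to three decimals and print p-values below 0.001 as
"<0.001"; the JSON report keeps full precision.

## Responder signatures

The two change scores are z-scored by full-sample mean/SD and clustered by
Ward's minimum-variance linkage (scipy implementation; deterministic for a
fixed input order). k is selected over 2–4 by mean silhouette, discarding
candidates whose smallest cluster is below `min_cluster_size` (default 5 —
large enough to rule out outlier-pair clusters in a 27-athlete cohort,
small enough to admit any plausible responder subgroup; if every candidate
trips the guard the overall silhouette maximum is returned with a warning).
Note that greedy agglomeration does not guarantee the globally optimal
k-partition; the test suite verifies exact agreement with an exhaustive
minimum-WSS oracle on structured data and a small optimality gap otherwise.

Stability uses bootstrap resampling of athletes: each replicate refits Ward
(same k) on the resample **in the original standardized space** (the
original scaler is reused — re-standardizing per replicate would break the
geometry in which original athletes are compared to bootstrap centroids),
computes centroids, assigns every original athlete to the nearest centroid
(Euclidean — Ward's natural geometry; ties to the lowest cluster id), and
aligns bootstrap labels to the original solution by *optimal* (not greedy)
maximum-overlap assignment on the k × k contingency table. Agreement is
summarized by the adjusted Rand index and per-original-cluster Jaccard
similarity `|A∩B|/|A∪B|`, each with percentile 95% intervals over 2,000
replicates. A replicate in which a mapped cluster captures no original
athletes is retained with Jaccard computed on the realized (possibly empty)
set. With resampling disabled the pipeline returns ARI = Jaccard = 1
exactly, a structural identity used as a self-check.

Group–signature association: Pearson χ² on the cluster × group table,
referenced to a 100,000-permutation null obtained by relabeling group
assignments (margins are permutation-invariant, so expected counts are
computed once).

## Prediction models

Features: arm indicators with CG as reference (the control is the natural
baseline level), a female indicator, and four standardized continuous
predictors (years of training, best 50 m time in *seconds* — larger =
slower, relevant when interpreting signs — and the baseline upper/lower
composites). The high-responder class is the cluster with the larger mean
total composite change.

Ridge (intercept unpenalized, features pre-standardized) and L2-logistic
models select their penalty over a 25-point log-spaced grid spanning
1e−3–1e3 by explicit leave-one-out refitting (squared error / log-loss).
Reported: LOO RMSE and cross-validated R² = 1 − SS_loo/SS_total; LOO
accuracy (0.5 threshold) and mean log-loss in nats. Coefficient uncertainty:
case-resampling bootstrap (default 2,000 replicates, penalty fixed at the
selected value), percentile 95% intervals and two-sided bootstrap
p = 2·min(frac ≤ 0, frac ≥ 0) for the ridge coefficients; logistic
replicates in which a class vanishes are redrawn. Predicted high-responder
probabilities per arm are evaluated at mean covariate values, with sex
entered as its sample proportion (a fractional indicator). Pairwise
log-odds contrasts between arms carry bootstrap intervals.

## Seeding and problem sizes

One master seed drives named child streams (simulation, each permutation
test, each bootstrap, stability, predictors), so stages are independently
reproducible and rerunning one stage does not perturb another. Package
defaults are the full-scale procedure counts (100,000 permutations, 20,000
bootstrap CIs, 2,000 stability replicates, 2,000 coefficient bootstraps); a
full default run on a 27-athlete cohort takes well under a minute. The test
suite exercises the same code paths at reduced counts (hundreds to a few
thousand resamples, Monte-Carlo-error-aware tolerances) and uses cohorts of
n = 1,000–4,000 per arm for parameter-recovery checks.

## Known limitations

* The generator's stable-offset noise model cannot represent test–retest
  measurement error within a swimmer; composite change scores are
  noise-free apart from finite-sample loading/SD estimation.
* Silhouette-guided Ward clustering inherits greedy agglomeration's lack of
  global optimality, and responder signatures remain sensitive to feature
  choice and scaling.
* With arm allocation among the predictors, the prediction models largely
  re-express between-group effects; they are exploratory descriptions, not
  validated prognostic models.
* The percentile bootstrap undercovers slightly at n = 9 per group; the
  coverage test in the suite documents this rather than hiding it.
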