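# respsig

Responder-signature analysis for three-arm dry-land training trials in
swimmers (or any small parallel-group trial with multi-indicator power
testing at Pre/Mid/Post).

Group-mean contrasts hide who actually responds to a training stimulus.
`respsig` implements a construct-based responder analysis for trials that
randomize athletes to maximal strength training (MSTG), plyometric training
(PTG) or an active control (CG) and measure six land-based power indicators
— bench press average power and medicine-ball throw (upper limb); CMJ, SJ,
DJ and SLJ (lower limb) — at three time points:

1. **Baseline-anchored composites.** Within each domain, Pre indicators are
   standardized by their own mean/SD and a one-component PCA is fitted on the
   baseline correlation matrix. The unit-norm loading vector **w** (oriented
   positive) is frozen; the composite at any time point is the raw projection
   `score_i = Σ_j w_j (x_ij − μ_j^pre)/σ_j^pre`. Responsiveness is the change
   score ΔUpper = Upper_post − Upper_pre (likewise ΔLower).
2. **Between-group inference.** For each endpoint and group pair: the mean
   difference, a stratified-bootstrap percentile 95% CI (20,000 resamples),
   a two-sided label-permutation p-value (100,000 permutations; exact
   enumeration for tiny pooled samples), Hedges g with the small-sample
   correction `J = 1 − 3/(4·df − 1)`, and Holm step-down adjustment across
   the three pairwise contrasts within each endpoint.
3. **Responder signatures.** Ward-linkage hierarchical clustering of the
   standardized (ΔUpper, ΔLower) vector; k chosen over 2–4 by silhouette
   with a small-cluster guard; 2,000-replicate bootstrap stability (refit on
   the resample, assign all original athletes to bootstrap centroids in the
   original standardized space, align by optimal maximum-overlap matching,
   summarize by adjusted Rand index and cluster-wise Jaccard similarity);
   permutation chi-square for the group × cluster association.
4. **Exploratory prediction.** Ridge regression of ΔUpper/ΔLower and an
   L2-logistic model of high-responder membership on arm indicators, sex,
   years of training, best 50 m time and baseline composites, with the
   penalty chosen by leave-one-out cross-validation and coefficient
   uncertainty from case-resampling bootstrap.

A seeded synthetic-cohort generator (`respsig.simulate`) reproduces the
cohort structure this pipeline is validated against (3 × 9 swimmers,
group-wise composite-change distributions, within-domain baseline indicator
correlations, covariate distributions), so the whole pipeline is testable
without any external data.

## Worked example

```bash
respsig run --simulate --seed 1 --out results/demo
```

runs the full pipeline on a simulated default cohort and prints

```
selected k = 2 (silhouette 0.636, sizes (18, 9))
ARI mean 0.849, chi2 27.000
outputs in results/demo
```

meaning the change space splits into a high-responder cluster (here, all 18
MSTG and PTG swimmers) and a low-responder cluster (the 9 controls), that
the two-cluster solution is highly reproducible under resampling (mean
adjusted Rand index 0.849; 1.0 would be identical partitions in every
replicate), and that signature membership is strongly associated with the
assigned training arm (Pearson χ² = 27.0 on the 2 × 3 cluster-by-group
table, permutation p < 0.001).

`results/demo/` then contains `table_descriptives.csv` /
`table_contrasts.csv` (per-group means, SDs, t-based 95% CIs; pairwise mean
differences with bootstrap CIs, Holm-adjusted permutation p-values and
Hedges g — in this run ΔUpper MSTG vs CG = 0.621 [0.561, 0.679], p < 0.001,
g = 8.7), cluster selection/profile/stability tables, the cluster-by-group
contingency table, figures (change-space scatter, silhouette-by-k, ARI
histogram) and `report.json` with everything at full precision. The same
analysis runs on a real cohort CSV via `--input panel.csv` (schema:
`swimmer_id, group, sex, age_years, years_training, best_50m` plus
`<indicator>_<pre|mid|post>` columns).

From Python:

```python
from respsig import (SimulationConfig, generate_cohort, fit_baseline_pca,
                     compute_deltas, run_contrasts)
from respsig.simulate import INDICATORS

panel = generate_cohort(SimulationConfig(seed=1))
upper = fit_baseline_pca(panel, "upper", INDICATORS["upper"])
lower = fit_baseline_pca(panel, "lower", INDICATORS["lower"])
delta = compute_deltas(upper, lower, panel)
results = run_contrasts(delta, n_perm=100_000, n_boot=20_000, seed=1)
```

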