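# coarsematch

Matching designs and post-matching analysis for observational cohort
studies, built to probe a specific methodological question: **when does a
matched design justify an unadjusted analysis?**

Coarsened exact matching (CEM) bins covariates, matches exactly on the bins,
and is often treated as if it reproduced a randomized block design — inviting
unadjusted analyses such as McNemar's test on the matched pairs. But CEM
balances only the *coarsened* scale C(X); inside a stratum, treated and
control subjects can still differ systematically in X itself. That residual
within-stratum imbalance,

    delta_c = E[X | T=1, C(X)=c] - E[X | T=0, C(X)=c],

is confounding that no increase in sample size removes, and it grows with the
coarseness of the bins. `coarsematch` implements the designs (exact matching,
CEM with equal-width binning, propensity-score caliper matching), the
post-matching estimators (an OLS model suite, the McNemar discordant-pair
odds ratio b/c, the Mantel–Haenszel common OR, and conditional logistic
regression for 1:1 pairs fit by step-halving Newton on the pair-difference
likelihood), balance/retention diagnostics, and seeded replication harnesses
that measure how estimator bias and model dependence respond to the
coarsening level.

Two synthetic cohort families drive the harnesses:

* **Continuous outcome** — discrete confounder X1 ∈ {0..10}, binary X2,
  logistic treatment model and linear outcome model both containing X1,
  X1², X2 and X1·X2 terms, constant additive treatment effect τ = 1.5.
* **Binary outcome** — X1 ~ Normal, X2 ~ Bernoulli(0.5), logistic treatment
  model `logit P(T=1) = γ0 + 0.15·X1 − 0.05·X1² + 0.1·X2 + 0.08·X1·X2` and
  outcome model `logit P(Y=1) = α0 + log(1.5)·T − 0.1·X1 + 0.08·X1² −
  0.15·X2 − 0.02·X1·X2` (true conditional OR 1.5), with γ0 and α0 found by
  root-finding so that ≈30% of subjects are treated and ≈40% have events.

## Worked example

Calibrate the binary-outcome cohort's intercepts, then run the coarsening
experiment at three bin counts (100 replications of n = 10,000):

```
$ coarsematch calibrate --seed 7
treatment intercept: -0.560603
outcome intercept:   -1.207135

$ coarsematch study2 --reps 100 --n 10000 --seed 7 --bins 5,10,50
 K         method  mean  mc_se  n_included  n_excluded
 5 clogit_correct 1.491  0.008         100           0
 5      clogit_x1 1.290  0.006         100           0
 5        mcnemar 1.293  0.006         100           0
10 clogit_correct 1.496  0.008         100           0
10      clogit_x1 1.427  0.008         100           0
10        mcnemar 1.428  0.008         100           0
50 clogit_correct 1.496  0.008         100           0
50      clogit_x1 1.492  0.008         100           0
50        mcnemar 1.492  0.008         100           0
```

Reading the table: the true conditional odds ratio is 1.5. The correctly
specified conditional-logistic model (`T, X1, X1², X1·X2`) stays at ≈1.5 at
every coarsening level. The unadjusted McNemar ratio and the misspecified
model (linear X1 only) are fine at 50 bins but drift toward the null as bins
get coarser — at K = 5 the McNemar estimate has collapsed to 1.29. Coarsening
shifts the modeling burden onto the outcome model: the coarser the bins, the
more the answer depends on getting that model right.

The continuous-outcome study makes the complementary point (`coarsematch
study1`): after exact matching, all seven outcome models — from
treatment-only up to the full quadratic-plus-interaction model — return the
*same* estimate within each replication (the matched arms have identical
empirical covariate distributions, so the treatment indicator is in-sample
orthogonal to every adjustment term), and propensity-score caliper matching
with a correctly specified treatment model is similarly model-insensitive.

The same machinery is available as a library:

```python
from coarsematch import (calibrate_spec, study2_spec, generate_cohort,
                         coarsen_equal_width, build_strata,
                         pair_within_strata, mcnemar_or, clogit)
import numpy as np

spec = calibrate_spec(study2_spec(), seed=7)
cohort = generate_cohort(spec, 10_000, seed=1)
bins = coarsen_equal_width(cohort.x1, 10)
sa = build_strata(np.column_stack([bins, cohort.x2]), cohort.t)
pairs = pair_within_strata(sa, seed=1)
print(mcnemar_or(pairs, cohort.y).estimate)
print(clogit(pairs, cohort, ("T", "X1", "X1^2", "X1*X2")).estimate)
```

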