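# Methods

## Scope and model

`coarsematch` studies post-matching inference in observational cohorts with
a binary treatment T, confounders X = (X1, X2), and either a continuous or
a binary outcome Y. Causal contrasts are the additive effect
τ = E[Y(1) − Y(0) | X] (constant by construction in the continuous family)
and the conditional odds ratio
ψ_cOR = [P(Y(1)=1|X)/P(Y(1)=0|X)] / [P(Y(0)=1|X)/P(Y(0)=0|X)]
(constant at 1.5 in the binary family). Identification assumes the usual
trio — consistency/no interference, strong ignorability given X, and
positivity. The marginal odds ratio is *not* targeted: odds ratios are
non-collapsible, so marginal and conditional versions differ even without
confounding, and all binary-outcome estimators here are conditional.

## Matching designs

**Exact matching** strata are the distinct values of (X1, X2). **CEM**
replaces X1 by its equal-width bin index over the per-dataset observed
range `[min(x1), max(x1)]` (left-closed bins, last bin closed; a constant
column maps to bin 0) and keeps X2 exact in the stratum key. Using the
observed range rather than a fixed theoretical one follows standard CEM
practice; it makes bins dataset-dependent but scale-equivariant. Strata
lacking either arm are dropped; retained controls carry weight n1k/n0k so
weighted controls equal treated per stratum, or subjects are randomly
1:1-paired within strata (uniform shuffles without replacement,
min(n1k, n0k) pairs, surplus unmatched). Including X2 in the stratum key is
deliberate: the binary-outcome "correct" conditional-logistic model then
needs no X2 main effect (it is constant within pairs), matching the model
list the harness fits.

**Propensity-score matching** fits the logistic treatment model by
Newton–Raphson (in-repo; converged when max |score| < 1e-8 or relative
log-likelihood change < 1e-10, with step-halving so the likelihood never
decreases; rank-deficient designs and perfectly separated fits raise
errors naming the offending term). Matching is greedy 1:1 nearest-neighbor
on logit ê(X) without replacement, treated processed in seeded random
order, caliper = 0.2 × SD of logit ê(X) over the pooled sample (sample SD,
ddof = 1; both the multiplier and, implicitly, the pooled convention are
configurable via `caliper_mult` and the fit object). Greedy rather than
optimal matching is the common default and is what the harness's claims
require; equidistant ties break to the lower control index. The nearest
unused control is found on a sorted array with union-find-style pointer
compression, so matching is effectively O(n log n).

## Estimators

* **OLS suite** M1–M7: Y regressed on an intercept, T, and nested covariate
  terms up to {X1, X1², X2, X1·X2}; the reported quantity is the
  coefficient on T. On an exactly matched 1:1 sample all seven coincide to
  numerical precision, because both arms then share the same empirical
  covariate distribution and T is in-sample orthogonal to every term.
* **McNemar odds ratio**: b/c over outcome-discordant pairs. No continuity
  correction: c = 0 < b is flagged `infinite`, b = c = 0 `undefined`, and
  flagged replications are excluded from averages and counted.
* **Mantel–Haenszel common OR**: Σ a_k d_k/n_k over Σ b_k c_k/n_k across
  retained strata, for many-to-many stratified data.
* **Conditional logistic regression** for 1:1 pairs, fit on the
  pair-difference representation: each outcome-discordant pair contributes
  log expit(s·d'β) with d the treated-minus-control term differences
  (d_T ≡ 1) and s = ±1 as the treated member is or is not the case;
  concordant pairs contribute nothing. Newton with step-halving (ascent
  guaranteed), convergence at max |score| < 1e-8, divergence (‖β‖∞ > 1e3)
  flagged as separation/non-convergence. With terms {T} alone the MLE is
  analytically b/c, which the tests exploit as an identity; the full fit is
  validated against an independent quasi-Newton maximizer and, during
  development, matched `survival::clogit` to six decimals.

## Synthetic cohorts

`study1_spec()` (continuous outcome): X1 ~ uniform on {0,…,10},
X2 ~ Bernoulli(0.5); treatment logit −2 + 0.4·X1 − 0.03·X1² + 0.4·X2 +
0.02·X1·X2; outcome mean 1.5·T + 0.5·X1 + 0.1·X1² + 1.0·X2 + 0.2·X1·X2 with
N(0, 1) noise. The structure (quadratic + interaction in both models,
constant effect 1.5) is the scientific requirement; the particular
coefficients are this package's documented defaults, chosen so that (a) a
naive treatment-only fit is visibly confounded (≈3.1 at n = 10⁵, >10 SEs
from 1.5) while (b) propensities stay well inside (0, 1), so exact matching
on 22 strata retains nearly all treated subjects at n = 10,000. Any
coefficients with these qualitative properties yield the same matched-design
conclusions; both term maps are overridable.

`study2_spec()` (binary outcome): X2 ~ Bernoulli(0.5) and X1 centred normal
with dispersion parameter 10, read as the **variance** by default
(SD = √10 ≈ 3.16); `x1_scale="sd"` selects the SD-10 reading. The default
was fixed empirically by running the coarsening experiment under both
readings: with SD 10 the quadratic outcome term concentrates events in the
X1 tails, matched strata yield only ~100–400 discordant pairs, and even the
correctly specified conditional-logistic estimate becomes unstable
(replication means 1.54–1.66), while the variance reading keeps it at
1.50–1.52 across all bin counts with the unadjusted McNemar ratio degrading
smoothly and monotonically with coarser bins — the behaviour the experiment
exists to exhibit. Under the variance default the *magnitude* of the
unadjusted-estimator collapse at very coarse binning is milder (≈1.31 at
K = 5) than under intermediate dispersions, because the within-bin
quadratic confounding contributions largely cancel for a symmetric,
moderately dispersed X1; the direction and ordering of the effects are
insensitive to the reading.

Intercept calibration: γ0 is root-found (Brent, on a 10⁶-draw Monte-Carlo
estimate of the marginal rate; bracket ±500 with an achievable-range check)
so that P(T=1) ≈ 0.30; α0 is then calibrated to P(Y=1) ≈ 0.40 marginally
over the joint (X, T) distribution induced by the already-calibrated
treatment model — the ordering matters and is fixed. Calibration runs once
per spec, never per replication; its residual on an independent 10⁶ draw is
within 1e-3, and the root itself carries Monte-Carlo noise of about 0.003,
so two independent calibrations agree to roughly two decimals.

What the generator does **not** emulate: covariate dimension beyond two,
missingness, unmeasured confounding, effect heterogeneity, survival/count
outcomes, or treatment models misspecified relative to the propensity fit.
Passing tests therefore demonstrate estimator behaviour under a known,
correctly structured data-generating process — not robustness of any design
on real data, where the propensity model is itself uncertain and CEM's
curse-of-dimensionality data loss is far more severe.

## Replication harnesses and problem sizes

One master seed feeds `numpy.random.SeedSequence.spawn`, giving independent
per-replication streams; identical configurations reproduce tables exactly.
Averaging of odds ratios is arithmetic by default (geometric available via
`or_scale="geometric"`); undefined/non-converged replications are excluded
and counted per cell. Default desk-scale sizes — n = 10,000 per cohort, 500
replications for the binary-outcome experiment (Monte-Carlo SEs ≈ 0.004 per
cell) and 200 for the continuous-outcome study — are the package's standard
operating point; full-scale runs (5,000 / 1,000 replications) are a
`reps=` argument away and change no conclusion, only the SEs.

## Known limitations

* Greedy caliper matching is order-dependent; the seeded random treated
  order makes it reproducible, not optimal.
* The conditional-logistic implementation covers 1:1 pairs only (the
  pair-difference likelihood); general m:n conditional likelihoods are out
  of scope, as are variances/CIs for all estimators — the harnesses compare
  point-estimate bias across replications.
* Arithmetic averaging of odds ratios carries a small Jensen-type upward
  skew (visible as ≈ +0.01 at 500 replications in the correct-model cells);
  it is kept as the default deliberately and the geometric option quantifies
  its size.
* `calibrate_intercept` trusts its Monte-Carlo draw; rates achievable only
  outside the ±500 logit bracket (pathological linear predictors) are
  reported as errors rather than extrapolated.
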