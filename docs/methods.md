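# Methods

## Setting and notation

Two samples from one target population measure the same binary health
condition.  The survey sample `S1` (size n1, design weights `w1`, inclusion
probabilities `π1` known by design) carries the gold-standard outcome `Y1`;
its weighted prevalence `p̂1 = Σ w1·Y1 / Σ w1` is design-unbiased for the
population prevalence `p1`.  The record sample `S2` (size n2 ≫ n1) carries an
error-prone outcome `Y2` and a nonprobability inclusion mechanism; it is made
representative with post-stratified weights `w2`, after which its weighted
prevalence estimates `p2 = P(Y2 = 1)` — which differs from `p1` by the
misclassification bias.  A linked subset `S_c ⊆ S1 ∩ S2` observes both
outcomes on the same subjects.  Logit-scale estimates are written
`y_j = logit(p̂_j)` with standard errors `σ_j`.  The covariance between the
two estimates is treated as ignorable because `|S1 ∩ S2| ≪ n2`.

## Mosteller pooling

The pooled estimate is `φ̂ = (k1·y1 + k2·y2)/(k1 + k2)` with `k1 = 1/σ1²`,
`k2 = 1/(τ̂² + σ2²)` and `τ̂² = (y1 − y2)²`, the consistent plug-in estimate
of the squared bias of `y2`.  These weights minimise the MSE among weighted
averages of the two logits; the same estimate is the posterior mean under a
flat prior on the true logit prevalence and a N(0, τ²) prior on the bias,
with posterior variance `σ1²(σ2² + τ²)/(σ1² + σ2² + τ²)`.  Credibility
intervals are `expit(φ̂ ± z·post_sd)` — highest-density on the logit scale
because the posterior there is normal.

Numerical conventions:

- Published confidence intervals are interpreted as symmetric on the logit
  scale; the SE is recovered as half the logit-width divided by the normal
  quantile.  Explicitly supplied (design-based) SEs take precedence over
  CI-derived ones.
- `y1 = y2` gives `τ̂² = 0` and `k2 = 1/σ2²` with no special-casing — the
  formula is continuous there.
- A weighted prevalence of exactly 0 or 1 raises an error rather than
  applying a silent continuity correction, since any correction would
  distort the pooling weights; callers may add pseudo-observations
  explicitly if they want one.
- The z-quantile is computed from the requested level (default 0.95, which
  reproduces the conventional 1.96).

Relative weights are reported as `(k1, k2)/(k1 + k2)` — the
logit-information scale.  When pooling published aggregates, results can
differ from values computed on microdata in the last printed digit, because
the inputs are themselves rounded; the demo command flags indicators where
both sources carry weight ≥ 0.1, the situation in which the two inputs'
rounding errors actually combine.

## Subject-level multiple imputation

Misclassification is modelled by two stratified logistic regressions on the
linked data,

    M1:  logit P(Y2 = 1 | Y1, z) = β0l + β1l' z + β2l Y1
    M2:  logit P(Y1 = 1 | Y2, z) = γ0l + γ1l' z + γ2l Y2

with independent Cauchy(0, 2.5) priors on all coefficients.  The strata
l = 1..4 are quartiles of the estimated inclusion probabilities — to the EHR
for M1 and to the survey for M2 — so the fits are unweighted but the design
information enters through the stratification.  The inclusion probabilities
are estimated by weighted logistic regressions: survey membership regressed
on the survey design factors over the (w2-weighted) EHR subjects, anchored so
that predictions match known design `π1` on average and known values always
take precedence; and EHR membership (known through linkage) regressed on
design factors over the (w1-weighted) survey subjects.  Only the ordering of
these predictions matters (quartiles), so the anchoring affects no estimate,
just the comparability of known and predicted values in one ranking.

Each of `M` imputations runs `B` alternating passes: impute missing `Y2`
(survey-only subjects) from M1, then missing `Y1` (EHR-only subjects) from
M2, treating the latest imputations as observed.  First-pass training sets
are the only place the two models differ from later passes: M1 starts on the
linked subset (the only subjects with both outcomes observed) and M2 on the
subjects with observed `Y1`; from the second pass both fit on everyone.
Observed outcomes are never overwritten — an assertion checks this on every
pass.  The per-imputation estimate is `p̂_m = Σ_{S2} w2·Ŷ1 / Σ w2` with
`Ŷ1` equal to the observed value wherever observed, and `s_m` its naive
logit-scale SE (weighted-ratio linearization, delta method).  The M logit
estimates are combined by Rubin's rules, `T = W + (1 + 1/M)B`, with the
Barnard–Rubin degrees of freedom for the t-interval; the complete-data df is
taken as the Kish effective EHR sample size minus one, `(Σw2)²/Σw2² − 1`,
the defensible survey choice when no likelihood-based df exists.  The
reported probability-scale point estimate is the mean of the `p̂_m`; the
interval is built on the logit scale around the mean of the `logit(p̂_m)`
and back-transformed.

Posterior draws use the normal approximation at the Cauchy-regularized mode
(mean = mode, covariance = inverse observed information) rather than MCMC —
the standard weakly-informative-prior GLM practice.  Predictors are
standardized before the prior is applied (binary columns centred, continuous
columns rescaled to SD 0.5) so one prior scale means roughly "per binary
flip or per two SDs"; coefficients are mapped back afterwards.  The mode is
found by damped Newton iteration with step halving; the Cauchy prior's
curvature at the origin keeps the system nonsingular under complete
separation or collinearity, so the fit always returns finite coefficients.

Defaults: `M = 30` imputations, `B = 10` passes, prior scale 2.5, confidence
level 0.95.  Because no formal convergence criterion exists for the
alternating passes, a diagnostic warns when an imputation's prevalence
trajectory still moves by ≥ 0.002 over the last three passes.  Random-number
discipline: one root seed; imputation m uses the substream
`SeedSequence(seed, spawn_key=(m,))`, so imputations are order-independent
and the whole run is bit-reproducible.

Degenerate cases are handled explicitly rather than silently: an empty
linked subset, a first-pass stratum with fewer than 10 training rows or a
single-class outcome, and an EHR-membership indicator without variation all
raise errors naming the offending piece.  One deliberate exception: when the
survey is fully linked (`S1 ⊆ S2`, the configuration with n12 = n1), no `Y2`
value is missing, so the M1 step and the EHR-inclusion model — whose outcome
would then have no variation — are skipped entirely; there is nothing for
them to do.

## Simulation framework

The generator emulates the two-source surveillance setting:

- Covariates: `x1 ~ Bernoulli(0.5)`, `x2 ~ N(0,1)` drive the outcomes;
  design factors `u1 ~ Bernoulli(0.5)`, `u2 ~ N(0,1)` drive selection; `x1`
  appears in both, so missingness is MAR but not MCAR.
- Outcomes: `(Y1, Y2)` have joint probabilities
  `(p11 : p10 : p01 : p00) = (e^(φ+η10+η01) : e^η10 : e^η01 : 1)` with
  `η10 = γ0 + γ1 x1 + γ2 x2`, `η01 = β0 + β1 x1 + β2 x2`, which makes both
  conditionals exactly logistic with common log odds ratio `φ`.  Computation
  is overflow-safe via max-subtraction.
- Intercepts are calibrated so the marginals hit the target prevalences
  (`p1 = 0.30`; `p2` between 0.30 and 0.35 depending on scenario), using an
  exact sum over `x1` and 60-node Gauss–Hermite quadrature over `x2`,
  solved by nested bisection (each marginal is strictly increasing in its
  own intercept), residuals < 1e−8.  The unreported slope values default to
  `γ1 = γ2 = β1 = β2 = 0.3` and `φ = 1.5`: the scenario targets, not the
  slopes, define the tabled settings — the slopes only shape the MAR
  structure — and all are overridable.
- Sampling: inclusion probabilities proportional to
  `expit(1 + u1 + u2 + 0.187·x1)` for both sources (a stated linear
  predictor cannot itself be a probability, so it is read through the
  inverse logit), normalized to the expected sample sizes and drawn by
  sequential Poisson sampling (fixed size, unequal probability).  Extra EHR
  members are then drawn uniformly among survey participants until the
  linked fraction reaches the configured overlap.  Survey weights are
  `1/π1`; `π2` is deleted afterwards (unknown in real record systems), as
  are `Y1`/`π1` outside the survey and `Y2` outside the EHR.
- Post-stratification cells for `w2`: the joint distribution of `u1`,
  population-quartile of `u2`, and `x1` (16 cells) against the realized
  population — exact cell weighting, no raking or collapsing; continuous
  factors are binned by quartiles to keep every cell identifiable.

What the generator does **not** emulate: real EHR misclassification that
depends on unmeasured institutional factors, informative linkage (here the
top-up is uniform among survey members), survey non-response, measurement
error in the gold standard itself, and more than two covariates per block
(though the vectors are config-extensible).  Passing tests therefore show
that the estimators behave as designed when their models are correctly
specified — not that the misclassification in any particular real record
system is captured.

The experiment runner regenerates the population each replicate (replicate r
uses seed `base + r`; a fixed-population mode is also provided), computes
the four estimators, and reports each estimator's mean and
`sqrt(mean((estimate − p1)²))` over replicates.  A replicate in which an
estimator raises (for example a too-thin first-pass stratum) is recorded and
excluded from that estimator's summary with an explicit failure count —
never silently dropped.

## Problem sizes used by the tests and the acceptance script

The full-scale study conditions (population 10⁷, EHR 100,000, 200
replicates, M = 30) are accepted by the same code path, but the packaged
runs use reduced scales chosen to keep the statistical comparisons
meaningful: replicated estimator comparisons use a population of 10⁶ with
an EHR of 20,000 (100–400 replicates); imputation-bias runs use a
population of 10⁵ with an EHR of 10,000, M = 10, B = 10 and 50 replicates.
Comparisons against published three-decimal figures allow one unit in the
last printed digit plus three Monte-Carlo standard errors of the rerun.

## Known limitations

- `τ̂² = (y1 − y2)²` is a noisy one-degree-of-freedom bias estimate; the
  pooled estimator's credibility interval conditions on it and can be
  anti-conservative when the sources disagree by an amount comparable to σ1.
- The imputation estimator inherits all of its models' assumptions;
  with weak misclassification predictors its intervals widen rather than its
  point estimate degrading (the cross-validated AUC diagnostic
  `cv_auc_misclassification` is provided to check this before trusting it).
- Post-stratification corrects selection only on the cell variables;
  selection on unmodelled factors correlated with the outcome remains.
- Pooling more than two sources, raking/calibration, replicate-weight
  variance estimation and finite-population corrections are out of scope.
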