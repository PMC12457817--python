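# Methods

`causalcf` estimates the average causal effect (ACE) of a binary
exposure X on a continuous outcome Y given a confounder vector W,

    ACE = E[Y^{X=1}] − E[Y^{X=0}],

identified under exchangeability, consistency and positivity by the
g-formula E[ E(Y|X=1,W) − E(Y|X=0,W) ].  The package provides two doubly
robust estimators built on estimated nuisance functions — the outcome
regression Ê(Y|X,W) and the propensity score ĝ(W) = P̂(X=1|W) — together
with a Super Learner for nuisance estimation, K-fold cross-fitting, and
a Monte-Carlo engine that evaluates the estimators on five synthetic
data-generating mechanisms emulating a birth-cohort study with
high-dimensional confounding.

## Estimators

**AIPW (one-step).**  With per-record predictions Ê1, Ê0 and ĝ,

    ψ̂ = (1/n) Σᵢ [ Ê1(wᵢ) − Ê0(wᵢ) + xᵢ(yᵢ−Ê1(wᵢ))/ĝ(wᵢ)
                                  − (1−xᵢ)(yᵢ−Ê0(wᵢ))/(1−ĝ(wᵢ)) ].

The bracketed per-record terms are the influence contributions; the
variance estimate is their empirical variance divided by n,
`se² = Σ(termᵢ − ψ̂)² / (n(n−1))`, and 95% intervals are ψ̂ ± 1.96·se.
AIPW is not a substitution estimator and can leave the natural parameter
space; such replicates are returned as-is and flagged downstream (see
*Stability exclusions*).

**TMLE.**  The bounded continuous-outcome recipe: Y and the initial
predictions are mapped to [0, 1] by the observed outcome range (a, b);
an intercept-free logistic fluctuation of the scaled predictions along
the clever covariate H(X, W) = X/ĝ − (1−X)/(1−ĝ), with offset
logit(Ê(X,W)), yields a single coefficient ε̂ solving the
efficient-influence-function score equation (Newton iterations to
|score| < 1e-11).  Targeted predictions Ê1*, Ê0* are back-transformed
and averaged: ψ̂ = mean(Ê1* − Ê0*).  The variance uses the same
influence-function form with the targeted predictions.  Because the
targeted predictions live in [a, b], the estimate always respects the
observed outcome range — the stability asymmetry relative to AIPW.

Numerical choices: scaled predictions *outside* [0, 1] are clipped to
[1e-4, 1−1e-4] (counted and reported); values inside the unit interval
are preserved up to a 1e-12 logit guard, so predictions exactly at the
outcome bounds remain effectively fixed points of the fluctuation.  A
degenerate outcome (zero range) is an error.

**Cross-fitting.**  The sample is split into K folds of near-equal size,
stratified by exposure (at n = 200 with ~25% exposure prevalence,
unstratified splits can produce complements with no exposed records —
those still raise an explicit error advising fewer folds).  Both
nuisance models are fitted on each fold-complement and evaluated on the
held-out fold.  AIPW pools the out-of-fold influence terms across folds;
TMLE performs the targeting *within each held-out fold* (on the common
global outcome range) and averages fold estimates weighted by fold size.
In both cases `se²` is the sample variance of the pooled out-of-fold
influence terms centred at the overall estimate, divided by n.  This
single-split EIF variance is the default; fold-averaged variants were
considered and rejected for simplicity since they agree to first order.

**Propensity truncation.**  Estimated propensity scores are truncated at
their empirical 5th and 95th percentiles (linear-interpolation
quantiles).  Under cross-fitting the percentiles are computed within
each held-out prediction vector, preserving the out-of-sample character
of the predictions; pooled truncation is available via a flag.

## Super Learner

Nuisance models are fitted by cross-validated convex stacking: every
base learner is fitted on each complement of a V-fold split (V = 10 by
default, stratified by the target for classification), the out-of-fold
prediction matrix is assembled, and weights are chosen on the
probability simplex minimizing the cross-validated loss — squared error
for the outcome regression, mean negative Bernoulli log-likelihood for
the propensity score.  Non-negative least squares warm-starts an SLSQP
polish; the best single learner is always a candidate, so the ensemble's
CV loss never exceeds that of any library member.  A learner that raises
during fitting is dropped with a logged warning; the library fails only
if every member does.

Two shipped libraries:

* **reduced** — GLM, GLM with pairwise interactions, ridge-penalized GLM
  (a shrinkage analogue of a weakly informative Bayesian GLM), a
  spline-basis additive model (cubic B-spline expansion + penalized
  GLM), and lasso regression (LARS path with CV-chosen penalty for the
  regression task, L1-penalized logistic for classification).
* **full** — the reduced set plus random forest, histogram gradient
  boosting, a single-hidden-layer neural network (16 units, on
  standardized inputs) and a hinge-basis adaptive-spline learner
  (piecewise-linear basis with knots at the 25/50/75% quantiles, L1
  selection) in the spirit of multivariate adaptive regression splines.

Hyperparameters are fixed defaults, documented in
`causalcf.superlearner.build_estimator`; no tuning or explicit variable
screening is performed.  Small `glm` and `glm-lasso` presets support
fast, correctly specified simulation runs.

## Data-generating mechanisms

Five mechanisms, all with a ~25% marginal exposure prevalence (the
analogue of a top-quartile dichotomized biomarker), unit residual SD and
outcome mean centred at zero:

| name       | p  | continuous | interactions & non-linear terms | interaction scale |
|------------|----|------------|---------------------------------|-------------------|
| simple-1   | 14 | 13         | none                            | —                 |
| complex-1a | 14 | 13         | yes                             | 2                 |
| complex-1b | 14 | 13         | yes                             | 4                 |
| simple-2   | 87 | 78         | none                            | —                 |
| complex-2  | 87 | 78         | yes                             | 1                 |

Confounders are generated sequentially — binary variables first
(Bernoulli-logistic, prevalences in [0.05, 0.5]), then unit-variance
Gaussians — each depending on up to three previously generated columns,
giving mutual dependence of mixed-type confounders.  The exposure is
Bernoulli with a logistic linear predictor; the outcome is Gaussian.
Complex mechanisms add two-way interactions (confounder–confounder in
both models, exposure–confounder in the outcome model) and non-linear
terms; the interaction-scale column multiplies all interaction
coefficients in both models.  A simple mechanism is the exact
zero-interaction restriction of its complex sibling: zeroing the
interaction and non-linear blocks reproduces it byte-for-byte under the
same seed.

All base coefficients are fixed, versioned constants drawn once from a
named seed: dependence coefficients uniform on ±0.30 (small set) /
±0.25 (large set); main effects ±0.30 / ±0.12; interaction coefficients
±0.08 / ±0.04 (confounder–confounder) and ±0.10 / ±0.05
(exposure–confounder); the complex small set carries 10
confounder–confounder and 5 exposure–confounder pairs, scaled
proportionally (62 and 31) for the large set.  Non-linear terms are
squares and log(|z|+1) transforms of four (small) / twelve (large)
designated continuous confounders — the basis is a package choice, since
only the presence of non-linearity is part of the design.  Magnitudes
were chosen so that the total outcome SD stays near 1.2 (a standardized
outcome with moderate confounder signal) and propensity scores stay away
from 0/1 in the simple mechanisms.  A multinomial-logit categorical
family (emitted as indicator columns) is implemented but unused in the
shipped presets so that the generated matrix has exactly p columns.

**Calibration.**  The outcome intercept is re-centred so the marginal
mean of Y is 0; because Y is linear in its coefficients this is a single
linear solve over one large simulated (W, X) sample (sampling error
≪ the 0.005 tolerance at the 250k–400k sample sizes used).  The exposure
main effect is calibrated per sample size so that the null of zero ACE
is rejected in 80% ± 3% of replicate datasets, by bisection over 400
replicates with common random numbers (only the outcome depends on the
effect coefficient, so the per-record influence terms are affine in it
and the search is deterministic).  The rejection test is the efficient
one-step analysis evaluated at the *exactly specified* nuisance
functions — the true conditional means and true propensity score, known
under simulation.  A feasible analysis that refits ~p parametric
nuisance parameters was rejected for this purpose: at p = 87 with
n = 200–500 its type-I error is 26–54% (overfitted outcome residuals
shrink the EIF variance), which would confound the power target with
finite-sample size distortion; the idealized test has nominal size
(measured 5.3% at p = 87, n = 200) in every scenario and makes the
calibrated effect monotone in n.  Pre-computed calibrated coefficients
for the 20-cell grid ship as constants, reproducible with
`causalcf calibrate`.

**Truth.**  The true ACE of each calibrated mechanism is evaluated
empirically as the average difference of the noise-free
potential-outcome conditional means over a single large confounder
sample (10⁶ records, chunked; noise-free means remove residual
Monte-Carlo error relative to drawing noisy potential outcomes).  For
simple mechanisms the ACE equals the exposure coefficient exactly
(linear, no effect modification), which serves as an internal
consistency check.

## Performance measures

Per scenario (mechanism × n × method × library × folds), over R kept
replicates: bias (mean ψ̂ − θ), relative bias (100·bias/θ; undefined at
θ = 0), empirical SE (SD of ψ̂), model SE (√mean(se²) — the
root-mean-variance convention of the standard simulation-study
tutorials), relative error in model SE (100·(modSE/empSE − 1)), coverage
of the 95% Wald interval, and power (|ψ̂| > 1.96·se).  Each measure
carries its Monte Carlo SE: binomial for coverage/power
(√(c(1−c)/R)), empSE/√R for bias, empSE/√(2(R−1)) for the empirical SE,
a delta-method form for the model SE and the SE ratio.  2000
replications keep the MCSE of 95% coverage at ≤ 0.5 percentage points;
the shipped CI-scale grids use 200–500 replications.

**Stability exclusions.**  Cross-fitted AIPW occasionally produces wild
replicates.  Before summarizing, replicates with se > 10 × median(se) or
|ψ̂| > 5 × |median(ψ̂)| (medians over the scenario's successful
replicates) are excluded — by default for AIPW only, since TMLE's
boundedness prevents the pathology; a flag extends the filter, and
exclusion and failure counts are always reported separately.

## Scope of the synthetic experiments

The generators emulate the *structure* of a real early-life cohort
confounding problem — mixed dependent confounder types, a dichotomized
exposure at 25% prevalence, small-to-moderate n against p = 14 or 87 —
but not its exact fitted coefficients, missing data, measurement error,
or selection. Passing tests therefore demonstrate the estimators'
statistical properties under known mechanisms of realistic shape, not
performance guarantees for any particular applied dataset.  The applied
entry point (`causalcf analyze`) refuses missing data and non-binary
exposures rather than imputing or coercing.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the power calibration at
its design scale (400 replicates for calibration and 400 fresh ones for
verification) and the coverage experiment at 500 replicates of n = 1000
with the glm+lasso library — enough for a two-MCSE coverage band of
about ±1.95 points.  The full 2000-replicate, all-scenario grid is
driven from a YAML config (`causalcf simulate`) and is intended for a
long-running batch job rather than a CI cycle.

## Known limitations

* Single cross-fitting only (no double cross-fitting, no aggregation
  over repeated random splits).
* Binary exposures and the ACE difference only; no missing-data
  handling.
* The supplementary fitted coefficients of the motivating cohort are
  not public; the shipped mechanisms are structural stand-ins with
  documented, versioned defaults (all overridable).
* "Bayesian GLM" is approximated by ridge shrinkage rather than full
  posterior sampling.
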