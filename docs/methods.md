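# Methods

## Model

The exponential power (EP) lifetime distribution has density

    f(t | γ, α) = (γ/α^γ) t^(γ−1) exp[(t/α)^γ] exp[1 − exp((t/α)^γ)],  t ≥ 0,

with dimensionless shape γ > 0 and scale α > 0 in the units of the
recorded times.  It is the same law as `scipy.stats.exponpow(b=γ,
scale=α)` (used as an independent oracle in the test suite).  Key
structural facts the package relies on:

* hazard `h(t) = (γ/α^γ) t^(γ−1) exp[(t/α)^γ]`, increasing for γ ≥ 1 and
  bathtub-shaped for 0 < γ < 1 with minimum at
  `t0 = α((1−γ)/γ)^(1/γ)`; as t → 0 the hazard diverges when γ < 1
  (infant-mortality pole) and equals 1/α when γ = 1;
* closed-form quantile `t = α[log(1 − log(1−u))]^{1/γ}`, so random
  variates come from the inverse-CDF transform of a seeded uniform
  generator (no attempt is made to reproduce any other software's RNG
  stream).

A complete sample contributes Σ log f(tᵢ); a right-censored observation
contributes the log-survival `log R(t) = 1 − exp((t/α)^γ)`.  The
regression variant ties the scale to covariates through the log-linear
link `log α(xᵢ) = β₀ + βᵀxᵢ` (an accelerated-failure-time-style model:
covariates rescale time), with a common shape γ.  Ties between event
and censoring times need no special handling in a parametric likelihood.

## Priors and parameterization

Positive parameters carry half-Cauchy(scale 25) priors — a
weakly-informative default for scales, applied to the shape as well;
regression coefficients carry N(0, 1000) priors, read as variance 1000
(sd ≈ 31.6; at these sample sizes the distinction from sd 1000 is
numerically negligible, but it is fixed here once).  Optimization and
sampling run on the unconstrained scale (log γ, log α; coefficients
untransformed).  Deliberately, **no Jacobian term** is added for the log
transform: the objective is `log L(exp u) + log p_HC(exp u)`, i.e. the
half-Cauchy prior is evaluated at the natural-scale parameter while the
search runs in u.  This matches the reference analyses this package
reproduces; it is equivalent to a slightly different (still proper)
prior on u, and all downstream summaries are documented against this
convention.  The deviance monitored per draw is −2 × log-likelihood,
priors excluded.

## Laplace approximation

The posterior mode is found by Nelder–Mead (standard
reflection/expansion/contraction coefficients 1, 2, 0.5, 0.5) with
simplex spread tolerance 1e−5, starting from the all-zero unconstrained
vector — a safe generic start under these priors.  BFGS is offered; it
is preceded by a coarse simplex stage because finite-difference
gradients are useless when the start sits astronomically far below the
mode (the all-zero start with data on a scale of 30 is ~1e17 log-units
deep).  Non-convergence flags the result rather than raising, and the
iterate trace is kept for convergence plots.

The covariance is the inverse of the central finite-difference Hessian
of the negative log-posterior at the mode, with per-coordinate steps
`h_k = max(1e−4, 1e−4 |θ̂_k|)`; the inverse goes through a Cholesky
solve, with escalating diagonal jitter (flagged) if the Hessian is not
positive definite and a hard error if jitter cannot rescue it.
Asymptotic interval summaries are mode ± 1.959964 sd.  First-order
Laplace expectations are `E g(θ) ≈ g(θ̂)`.

Sampling importance resampling (SIR) draws `n_draws` (default 10,000)
points from N(mode, covariance), weights them by
`exp(log posterior − log proposal)` and resamples `n_keep` (default
1000) with replacement — weights can concentrate at small `n_draws`, so
replacement is the safe choice.  The effective proposal size `1/Σw²` is
reported as a degeneracy diagnostic.  SIR targets the posterior itself
and is unbiased for it.

## Independence Metropolis

The IM chain proposes from the fixed Gaussian N(mode,
`proposal_scale²` × covariance) (a Student-t proposal with configurable
df is available for heavy-tailed robustness, off by default), starts at
the proposal mode, and keeps every `thinning`-th state; because of the
warm start no burn-in is discarded by default (a `burnin` fraction is
available in the summaries), and no automated stationarity detection is
attempted at these model sizes.

Two acceptance rules are implemented:

* **exact** (library default): `min(1, p(u*|y) q(u) / (p(u|y) q(u*)))`
  — the textbook independence sampler; its stationary law is the
  posterior.
* **reference**: the proposal-density ratio enters with inverted sign,
  `min(1, p(u*|y) q(u*) / (p(u|y) q(u)))`.  This reproduces, to print
  precision, the published analyses (run with the LaplacesDemon R
  package's IM sampler) that this package re-implements.  A Metropolis
  chain whose acceptance function is `f(u) = p(u|y)q(u)` driven by an
  independence proposal q has stationary density ∝ f·q = p(u|y)q(u)² —
  a mode-anchored sharpening of the posterior.  When q matches the
  posterior's Gaussian limit, the stationary spread is ≈ 1/√3 of the
  posterior's, and reported posterior SDs shrink accordingly; posterior
  means are pulled toward the Laplace mode.  The rule is provided for
  reproducibility of published tables; new analyses should use
  **exact** (or SIR, which is unbiased).

Chains are bit-reproducible given (seed, iterations, thinning,
proposal).  An acceptance rate below 1% raises a warning (badly
mismatched proposal).

## Summaries and functionals

Per column (parameters, deviance, monitors): mean, SD, empirical
2.5/50/97.5% quantiles, effective sample size by Geyer's
initial-positive-sequence truncation of the autocorrelation sum (capped
at the chain length; a constant column reports the chain length with a
warning), and MCSE = SD/√ESS.  Posterior functionals — hazard or
reliability at a fixed time, the change-point t0, burn-in/replacement
times for a failure-rate threshold — are evaluated on the kept draws
mapped back to the natural scale; draws where a functional is undefined
(t0 with γ ≥ 1, thresholds below the hazard minimum) are recorded as
NaN, summarized over the defined subset, and the defined fraction is
reported.

## Burn-in / replacement solver

`solve_hazard_times` solves h(t) = r by Brent's method (tolerance 1e−12
on t plus machine-level relative tolerance) on brackets [ε, t0] and
[t0, T] with geometric (factor-2) expansion of T until the hazard
exceeds the threshold; the smaller root is the optimum burn-in time,
the larger the optimum replacement time.  For γ ≥ 1 at most one root
exists and is returned as the replacement time.  A threshold below the
hazard minimum raises a no-solution error; a threshold exactly at the
minimum returns both roots equal to t0.

## Synthetic data

`simulate_dataset` emulates the reference study conditions and is the
source of all test data beyond the three bundled datasets: the
no-covariate model draws n = 15 lifetimes from EP(γ = 1, α = 30) by
inverse CDF; the regression model draws a single Uniform(0, 1) covariate
and lifetimes with γ = 1, β₀ = 1, β₁ = 2, n = 15.  Optional fixed-time
censoring replaces every lifetime above c with (c, status 0).  The
generator reproduces the data-generating *law* of the reference
simulated datasets but not their specific realizations (their RNG stream
is not portable), so regression checks are parameter-recovery tests at
n = 200 (posterior mean within 3 posterior SD of truth) rather than
value matches.  What it does not emulate: covariate-dependent or random
censoring, left/interval censoring, model misspecification — passing
recovery tests therefore says nothing about robustness to those.

## Bundled datasets

`table1`: 15 lifetimes simulated from EP(1, 30), recorded to two
decimals with half-up rounding (so the 13th value is 23.13, the time at
which hazard/reliability posteriors are monitored in the examples).
`device`: 18 electronic-device failure times, complete.  `transistor`:
34 accelerated-life-test lifetimes in weeks, the last three (52)
right-censored.  The bundled values are checksummed; loading fails if
they are edited.

## Numerical choices

* All density work goes through the log form; the argument of the outer
  exponential is clipped at 709 (double overflow), so extreme-tail
  evaluations return huge-negative finite log-densities instead of
  overflowing, and points whose likelihood is non-finite map to log
  posterior −∞ (rejected) rather than raising.
* At t = 0 the density and hazard are returned as +∞ for γ < 1 (the
  pole is real); likelihoods require strictly positive times.
* CDF/quantile round-trips are exact to ~1e−9 only while F(t) is
  representably below 1 in doubles, i.e. exp((t/α)^γ) ≲ 36; beyond that
  F collapses to 1.0.
* CSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write → load is bit-exact.
* With a constant covariate column the regression model is identified
  only through β₀ + β₁c, but the proper priors keep the posterior
  proper and the mode finder still converges (the Hessian may be
  jittered and is flagged).

## Problem sizes

The bundled reproductions use the reference chain sizes: 10,000
iterations thinned by 10 for the simulated dataset, and unthinned
chains of 2000 (device) and 3000 (transistor) draws — matching the
published "2000/3000 MCMC simulations", which also makes this package's
MCSE a like-for-like gauge of the reference runs' Monte Carlo error.
Property and recovery tests use n = 200 samples and 1000-draw chains.

## Limitations

* Left- and interval-censoring are not supported; only right censoring.
* Single-chain tooling: no parallel chains or split-R̂ diagnostics (the
  warm-started IM chain at these model sizes mixes essentially
  immediately; ESS/MCSE are the operative diagnostics).
* The Laplace summaries are asymptotic; at n ≈ 15 they overstate the
  posterior spread of this skewed posterior relative to exact sampling
  (the tests assert only the observed ordering, Laplace SD ≥ MCMC SD).
* Marginal posterior densities are obtained by sampling, not by the
  (intractable) analytic marginalization integrals.
* No DIC/WAIC model comparison; the deviance is summarized per draw
  only.
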