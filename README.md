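# epbayes

Bayesian inference for the **exponential power (EP) lifetime model**, a
two-parameter distribution whose failure rate is bathtub-shaped — high
infant mortality, a stable middle life, then wear-out — for shape
parameters below one, and monotonically increasing otherwise.  The
package targets reliability engineers and biostatisticians fitting small
time-to-event datasets (complete or right-censored, with or without
covariates) who want full posterior uncertainty for the parameters *and*
for derived quantities such as the hazard curve, survival probabilities,
the hazard change-point, and optimum burn-in / replacement times.

## The model

Lifetimes follow the density

```
f(t) = (γ/α^γ) t^(γ-1) exp[(t/α)^γ] exp[1 − exp((t/α)^γ)],   t ≥ 0,
```

with shape γ > 0 and scale α > 0.  The reliability and hazard are

```
R(t) = exp[1 − exp((t/α)^γ)],      h(t) = (γ/α^γ) t^(γ-1) exp[(t/α)^γ].
```

For 0 < γ < 1 the hazard attains its minimum at the change-point
`t0 = α((1−γ)/γ)^(1/γ)`; solving `h(t) = r` below/above `t0` yields the
optimum burn-in and replacement times for a failure-rate criterion `r`.
The CDF inverts in closed form, `t = α[log(1 − log(1−u))]^{1/γ}`, which
drives the synthetic-data generator.

Inference is Bayesian with weakly informative priors — half-Cauchy(25)
on γ and α (and, in the regression variant with the log-linear link
`log α(x) = β₀ + β₁x`, normal N(0, 1000) priors on the coefficients).
The pipeline is:

1. **Laplace approximation** — Nelder–Mead (or BFGS) maximization of the
   unnormalized log-posterior on the log scale, covariance from the
   inverse finite-difference Hessian; optionally sampling importance
   resampling (SIR) for approximate posterior draws.
2. **Independence Metropolis (IM)** — an MCMC chain whose proposal is
   the fixed Gaussian Laplace approximation, with per-draw deviance
   (−2 log L) and monitored functionals, summarized by posterior mean,
   SD, MCSE, effective sample size and 2.5/50/97.5% quantiles.

Two IM acceptance rules are available: the standard (`"exact"`) rule,
and a `"reference"` compatibility rule reproducing the sampler semantics
of the R package (LaplacesDemon) used in the published analyses this
package re-implements — see `docs/methods.md` for exactly what that rule
samples and when to use which.

## Worked example

Three classic datasets ship with the package: `table1` (15 simulated
EP(1, 30) lifetimes), `device` (18 electronic-device failure times) and
`transistor` (34 accelerated-life-test lifetimes in weeks, 3
right-censored).  Fitting the device data:

```python
import epbayes as ep

sample = ep.load_dataset("device")
lp = ep.LogPosterior(sample)                  # half-Cauchy(25) priors
lap = ep.laplace_approximation(lp)
print(lap.summary().round(3))

chain = ep.run_im_chain(lp, lap, iterations=2000, thinning=1, seed=1,
                        acceptance_rule="reference")
ep.posterior_functional(chain, ep.changepoint_monitor(), "t0")
print(ep.summarize_chain(chain).round(3))
```

prints

```
            Mode     SD     LB  Median     UB
log.gamma -0.087  0.212 -0.502  -0.087  0.328
log.alpha  5.614  0.152  5.315   5.614  5.912

              Mean      SD   MCSE      ESS       LB   Median       UB  Defined
log.gamma   -0.097   0.126  0.004  885.427   -0.346   -0.103    0.148     1.00
log.alpha    5.612   0.085  0.003  690.662    5.432    5.612    5.779     1.00
Deviance   219.372   0.768  0.034  506.185  218.634  219.137  221.522     1.00
t0          32.072  20.462  0.940  474.192    1.877   29.747   79.730     0.78
```

The first table is the asymptotic (Laplace) summary of the
log-parameters: posterior mode with SD from the inverse Hessian.  The
second summarizes the 2000-draw IM chain: back-transformed, the
posterior means are γ ≈ 0.915 and α ≈ 274.6, so the device shows a mild
bathtub (γ < 1 in ~78% of draws, the fraction where the change-point
`t0` is defined — its posterior median is ≈ 30 time units).  `Deviance`
is −2 log-likelihood per draw; its mean (219.4) is the usual fit
summary.  With the fitted parameters, a failure-rate ceiling of 0.005
gives

```python
res = ep.solve_hazard_times(0.005, ep.EPParams(0.915, 274.62))
# burn-in 2.8, replacement 71.3 time units
```

The same pipeline is available from the shell:

```
epbayes fit --data device --method im --iterations 2000 --thinning 1 \
            --seed 1 --acceptance-rule reference --monitor changepoint
epbayes simulate --gamma 1 --alpha 30 --n 15 --seed 1
epbayes hazard-times -b 0.005 --gamma 0.915 --alpha 274.62
```

and as a scikit-learn estimator
(`ep.ExponentialPowerFitter(method="im").fit(X, y)`) for pipeline and
model-selection workflows.

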