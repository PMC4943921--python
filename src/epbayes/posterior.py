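"""Likelihoods, priors and the unnormalized log-posterior.

Two model kinds are supported:

* ``"null"`` — i.i.d. EP(gamma, alpha) lifetimes, parameters
  ``(log gamma, log alpha)`` on the unconstrained scale;
* ``"regression"`` — an accelerated-failure-time-style log-linear link
  on the scale, ``log alpha(x_i) = beta_0 + beta_1 x_i1 + ...``, with
  unconstrained parameters ``(beta_0, ..., beta_J, log gamma)``.

Right-censored observations contribute the log-survival probability
``log R(t) = 1 - exp((t/alpha)**gamma)``.

Priors are weakly informative: half-Cauchy(25) on each positive natural
parameter (gamma, alpha) and N(0, 1000) (variance 1000) on regression
coefficients.  Deliberately, *no* Jacobian term is added for the log
transform of the positive parameters: the objective maximized and
sampled is ``log L(exp(u)) + log p_HC(exp(u))``, i.e. the prior is
evaluated at the natural-scale parameter while optimization runs on the
log scale.  This is the parameterization under which the reference
posterior summaries in the documentation are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .data import LifetimeSample
from .distribution import _EXP_CLIP, EPParams

__all__ = [
    "PriorSpec",
    "RegressionParams",
    "ParameterLayout",
    "LogPosterior",
    "half_cauchy_logpdf",
    "loglik_complete",
    "loglik_censored",
    "loglik_regression",
    "log_prior",
    "log_posterior",
]

ModelKind = Literal["null", "regression"]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: half-Cauchy scale for positive parameters and
    normal moments for regression coefficients (scale = sd)."""

    hc_scale: float = 25.0
    beta_location: float = 0.0
    beta_scale: float = math.sqrt(1000.0)

    def __post_init__(self) -> None:
        if not (self.hc_scale > 0 and self.beta_scale > 0):
            raise ValueError("prior scales must be strictly positive")


@dataclass(frozen=True)
class RegressionParams:
    """Shape gamma plus coefficient vector (intercept beta_0 first)."""

    gamma: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be a positive finite real")
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(~np.isfinite(beta)):
            raise ValueError("beta must be finite")
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class ParameterLayout:
    """Ordering and transform between the unconstrained vector and the
    natural-scale parameters.  Positive parameters are stored as natural
    logs; coefficients are untransformed."""

    kind: ModelKind
    n_covariates: int = 0

    @property
    def names(self) -> list:
        if self.kind == "null":
            return ["log.gamma", "log.alpha"]
        return [f"beta[{j}]" for j in range(self.n_covariates + 1)] + ["log.gamma"]

    @property
    def dim(self) -> int:
        return 2 if self.kind == "null" else self.n_covariates + 2

    def to_natural(self, u: np.ndarray):
        u = np.asarray(u, dtype=float)
        if u.shape != (self.dim,):
            raise ValueError(f"expected a vector of length {self.dim}, got shape {u.shape}")
        if self.kind == "null":
            return EPParams(gamma=float(np.exp(u[0])), alpha=float(np.exp(u[1])))
        return RegressionParams(gamma=float(np.exp(u[-1])), beta=u[:-1].copy())

    def from_natural(self, params) -> np.ndarray:
        if self.kind == "null":
            return np.array([math.log(params.gamma), math.log(params.alpha)])
        return np.append(params.beta, math.log(params.gamma))

    def natural_arrays(self, draws: np.ndarray) -> dict:
        """Map an S x dim matrix of unconstrained draws to natural-scale
        arrays: {'gamma','alpha'} or {'gamma','beta'}."""
        draws = np.atleast_2d(draws)
        if self.kind == "null":
            return {"gamma": np.exp(draws[:, 0]), "alpha": np.exp(draws[:, 1])}
        return {"gamma": np.exp(draws[:, -1]), "beta": draws[:, :-1]}


def half_cauchy_logpdf(x, scale: float):
    """log of 2/(pi*scale*(1+(x/scale)^2)) for x >= 0."""
    x = np.asarray(x, dtype=float)
    return math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)


def _event_loglik_terms(t: np.ndarray, gamma: float, alpha: float):
    """Per-event contributions of the stable log-likelihood form."""
    z = np.exp(np.minimum(gamma * (np.log(t) - math.log(alpha)), _EXP_CLIP))
    return (
        math.log(gamma)
        - gamma * math.log(alpha)
        + (gamma - 1.0) * np.log(t)
        + z
        + 1.0
        - np.exp(np.minimum(z, _EXP_CLIP))
    )


def _censored_loglik_terms(t: np.ndarray, gamma: float, alpha: float):
    """log R(t) = 1 - exp((t/alpha)**gamma) per censored observation."""
    z = np.exp(np.minimum(gamma * (np.log(t) - math.log(alpha)), _EXP_CLIP))
    return -np.expm1(np.minimum(z, _EXP_CLIP))


def loglik_complete(data: LifetimeSample, params: EPParams) -> float:
    """Log-likelihood of a complete (uncensored) sample:

    n log g - n g log a + (g-1) sum log t + sum (t/a)^g + n - sum e^{(t/a)^g}
    """
    if np.any(data.status == 0):
        raise ValueError("sample contains censored observations; use loglik_censored")
    t, g, a = data.times, params.gamma, params.alpha
    n = t.size
    z = np.exp(np.minimum(g * (np.log(t) - math.log(a)), _EXP_CLIP))
    return float(
        n * math.log(g)
        - n * g * math.log(a)
        + (g - 1.0) * np.log(t).sum()
        + z.sum()
        + n
        - np.exp(np.minimum(z, _EXP_CLIP)).sum()
    )


def loglik_censored(data: LifetimeSample, params: EPParams) -> float:
    """Right-censored log-likelihood: events contribute log f, censored
    observations contribute log R.  Reduces exactly to
    :func:`loglik_complete` when every status is 1."""
    ev = data.status == 1
    total = _event_loglik_terms(data.times[ev], params.gamma, params.alpha).sum()
    if np.any(~ev):
        total += _censored_loglik_terms(data.times[~ev], params.gamma, params.alpha).sum()
    return float(total)


def loglik_regression(data: LifetimeSample, params: RegressionParams) -> float:
    """Log-likelihood with the log-linear scale link
    alpha_i = exp(beta_0 + beta_1 x_i1 + ...); censored observations
    contribute log R(t_i; gamma, alpha_i)."""
    if data.covariates is None:
        raise ValueError("regression likelihood requires covariates")
    if params.beta.size != data.n_covariates + 1:
        raise ValueError(
            f"expected {data.n_covariates + 1} coefficients (intercept first), "
            f"got {params.beta.size}"
        )
    g = params.gamma
    t = data.times
    eta = params.beta[0] + data.covariates @ params.beta[1:]  # log alpha_i
    z = np.exp(np.minimum(g * (np.log(t) - eta), _EXP_CLIP))
    ev = data.status == 1
    terms = np.where(
        ev,
        math.log(g) - g * eta + (g - 1.0) * np.log(t) + z + 1.0
        - np.exp(np.minimum(z, _EXP_CLIP)),
        -np.expm1(np.minimum(z, _EXP_CLIP)),
    )
    return float(terms.sum())


def log_prior(u: np.ndarray, layout: ParameterLayout, spec: PriorSpec) -> float:
    """Log prior density at the unconstrained point, evaluated on the
    natural scale for positive parameters (no Jacobian, by design)."""
    u = np.asarray(u, dtype=float)
    if layout.kind == "null":
        gamma, alpha = np.exp(u[0]), np.exp(u[1])
        return float(
            half_cauchy_logpdf(gamma, spec.hc_scale)
            + half_cauchy_logpdf(alpha, spec.hc_scale)
        )
    beta, gamma = u[:-1], np.exp(u[-1])
    lp = float(half_cauchy_logpdf(gamma, spec.hc_scale))
    lp += float(
        np.sum(
            -0.5 * math.log(2.0 * math.pi)
            - math.log(spec.beta_scale)
            - 0.5 * ((beta - spec.beta_location) / spec.beta_scale) ** 2
        )
    )
    return lp


class LogPosterior:
    """Callable unnormalized log-posterior on the unconstrained scale.

    Bundles a dataset, prior and model kind; returns ``-inf`` (never an
    exception) at points where the likelihood is non-finite, so that
    optimizers and samplers can simply reject them.
    """

    def __init__(
        self,
        data: LifetimeSample,
        prior: Optional[PriorSpec] = None,
        kind: Optional[ModelKind] = None,
    ) -> None:
        self.data = data
        self.prior = prior or PriorSpec()
        if kind is None:
            kind = "regression" if data.covariates is not None else "null"
        if kind == "regression" and data.covariates is None:
            raise ValueError("regression model requires covariates in the data")
        self.layout = ParameterLayout(kind, data.n_covariates if kind == "regression" else 0)

    @property
    def kind(self) -> ModelKind:
        return self.layout.kind

    @property
    def names(self) -> list:
        return self.layout.names

    @property
    def dim(self) -> int:
        return self.layout.dim

    def loglik(self, u: np.ndarray) -> float:
        params = self.layout.to_natural(u)
        if self.kind == "null":
            return loglik_censored(self.data, params)
        return loglik_regression(self.data, params)

    def deviance(self, u: np.ndarray) -> float:
        """-2 x log-likelihood (priors excluded), the per-draw fit monitor."""
        return -2.0 * self.loglik(u)

    def __call__(self, u: np.ndarray) -> float:
        u = np.asarray(u, dtype=float)
        if np.any(~np.isfinite(u)):
            return -math.inf
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                ll = self.loglik(u)
            except ValueError:  # e.g. exp-underflow of a positive parameter
                return -math.inf
            if not np.isfinite(ll):
                return -math.inf
            lp = ll + log_prior(u, self.layout, self.prior)
        return lp if np.isfinite(lp) else -math.inf


def log_posterior(
    u: np.ndarray,
    data: LifetimeSample,
    spec: Optional[PriorSpec] = None,
    model_kind: Optional[ModelKind] = None,
):
    """Functional form of :class:`LogPosterior`; returns
    ``(log_posterior, deviance)`` at the unconstrained point."""
    lp = LogPosterior(data, spec, model_kind)
    value = lp(u)
    dev = lp.deviance(u) if np.isfinite(value) else math.inf
    return value, dev
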