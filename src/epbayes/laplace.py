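"""Laplace approximation of the posterior.

Deterministically maximizes the unnormalized log-posterior on the
unconstrained scale (Nelder-Mead by default, BFGS optional), forms the
Gaussian approximation N(mode, H(mode)^-1) from the central
finite-difference Hessian of the negative log-posterior, and optionally
draws approximate posterior samples by sampling importance resampling
(SIR).  The Gaussian doubles as the proposal of the independence
Metropolis sampler in :mod:`epbayes.sampler`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .posterior import LogPosterior

__all__ = [
    "LaplaceFit",
    "ApproximationError",
    "find_mode",
    "hessian_covariance",
    "laplace_approximation",
    "laplace_expectation",
    "sir_resample",
]

_Z975 = 1.959964  # standard normal 97.5% quantile


class ApproximationError(RuntimeError):
    """The Gaussian approximation could not be formed (singular Hessian)."""


@dataclass
class LaplaceFit:
    """Posterior mode, covariance and convergence metadata.

    ``covariance`` is the inverse of the negative log-posterior Hessian
    at the mode; ``trace`` records the iterate path of the optimizer
    (one row per iteration) for convergence diagnostics.
    """

    mode: np.ndarray
    names: list
    covariance: Optional[np.ndarray] = None
    converged: bool = True
    n_iter: int = 0
    log_posterior: float = math.nan
    trace: Optional[np.ndarray] = None
    jittered: bool = False

    @property
    def sd(self) -> np.ndarray:
        if self.covariance is None:
            raise ApproximationError("covariance has not been computed")
        return np.sqrt(np.diag(self.covariance))

    def summary(self) -> pd.DataFrame:
        """Table of modes, asymptotic SDs and Gaussian 2.5/50/97.5%
        quantiles (mode +/- 1.959964 sd)."""
        sd = self.sd
        return pd.DataFrame(
            {
                "Mode": self.mode,
                "SD": sd,
                "LB": self.mode - _Z975 * sd,
                "Median": self.mode,
                "UB": self.mode + _Z975 * sd,
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mode": self.mode.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "sd": None if self.covariance is None else self.sd.tolist(),
            "converged": bool(self.converged),
            "iterations": int(self.n_iter),
            "log_posterior": float(self.log_posterior),
        }


def find_mode(
    logpost: Callable[[np.ndarray], float],
    dim: Optional[int] = None,
    init: Optional[np.ndarray] = None,
    method: str = "nelder-mead",
    tol: float = 1e-5,
    max_iter: int = 2000,
    names: Optional[list] = None,
) -> LaplaceFit:
    """Maximize the log-posterior; returns a :class:`LaplaceFit` without
    covariance (see :func:`hessian_covariance`).

    The default initial point is the all-zero unconstrained vector, a
    safe generic choice under the weakly informative priors.  Non-
    convergence within ``max_iter`` flags the result rather than raising.
    """
    if init is None:
        if dim is None:
            dim = getattr(logpost, "dim")
        init = np.zeros(dim)
    init = np.asarray(init, dtype=float)
    if not np.isfinite(logpost(init)):
        raise ValueError("log-posterior is not finite at the initial point")
    trace = [init.copy()]

    def neg(u):
        v = logpost(u)
        return math.inf if not np.isfinite(v) else -v

    method_key = method.lower().replace("_", "-")
    if method_key in ("nm", "nelder-mead"):
        res = minimize(
            neg,
            init,
            method="Nelder-Mead",
            callback=lambda xk: trace.append(np.array(xk)),
            options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
        )
    elif method_key == "bfgs":
        # gradient-based search needs a sane starting basin: the generic
        # all-zero start can sit astronomically far below the mode, where
        # finite-difference gradients are useless.  A coarse simplex
        # stage gets within the quadratic region first.
        coarse = minimize(
            neg, init, method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 1e-2, "maxiter": max_iter},
        )
        trace.append(np.array(coarse.x))
        res = minimize(
            neg,
            coarse.x,
            method="BFGS",
            callback=lambda xk: trace.append(np.array(xk)),
            options={"gtol": tol, "maxiter": max_iter},
        )
    else:
        raise ValueError(f"unknown optimization method {method!r} (use 'nelder-mead' or 'bfgs')")
    if names is None:
        names = getattr(logpost, "names", [f"p{i}" for i in range(init.size)])
    return LaplaceFit(
        mode=np.asarray(res.x, dtype=float),
        names=list(names),
        converged=bool(res.success),
        n_iter=int(res.get("nit", len(trace) - 1)),
        log_posterior=-float(res.fun),
        trace=np.vstack(trace),
    )


def finite_difference_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, base_step: float = 1e-4
) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate steps
    h_k = max(base_step, base_step * |x_k|)."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = np.maximum(base_step, base_step * np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def hessian_covariance(
    fit: LaplaceFit,
    logpost: Callable[[np.ndarray], float],
    base_step: float = 1e-4,
    max_jitter_tries: int = 8,
) -> LaplaceFit:
    """Fill in ``fit.covariance`` as the inverse negative-log-posterior
    Hessian at the mode, with escalating diagonal jitter if the Hessian
    is not positive definite (the fit is then flagged ``jittered``)."""
    H = finite_difference_hessian(lambda u: -logpost(u), fit.mode, base_step)
    H = 0.5 * (H + H.T)
    jitter = 0.0
    scale = max(np.abs(np.diag(H)).max(), 1.0)
    for attempt in range(max_jitter_tries):
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(H.shape[0]))
            inv_l = np.linalg.inv(L)
            fit.covariance = inv_l.T @ inv_l
            if attempt > 0:
                fit.jittered = True
                warnings.warn(
                    "Hessian was not positive definite; diagonal jitter applied",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return fit
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (attempt - 8)
    raise ApproximationError(
        "Hessian is singular even after jitter; the Gaussian approximation "
        "failed - consider a pure-MCMC fit with a hand-chosen proposal"
    )


def laplace_approximation(
    logpost: LogPosterior,
    init: Optional[np.ndarray] = None,
    method: str = "nelder-mead",
    tol: float = 1e-5,
    max_iter: int = 2000,
    base_step: float = 1e-4,
) -> LaplaceFit:
    """Mode search followed by the Hessian-based covariance."""
    fit = find_mode(logpost, dim=logpost.dim, init=init, method=method,
                    tol=tol, max_iter=max_iter, names=logpost.names)
    return hessian_covariance(fit, logpost, base_step=base_step)


def laplace_expectation(g: Callable[[np.ndarray], float], fit: LaplaceFit) -> float:
    """First-order Laplace estimate of a posterior expectation:
    E{g(theta)} ~ g(mode), accurate to O(1/n)."""
    return float(g(fit.mode))


def sir_resample(logpost, fit: LaplaceFit, n_draws: int = 10000,
                 n_keep: int = 1000, seed=None):
    """Sampling importance resampling from the Gaussian approximation.

    Draws ``n_draws`` points from N(mode, covariance), weights them by
    posterior/proposal, and resamples ``n_keep`` indices with
    replacement proportional to the normalized weights.  Returns
    :class:`~epbayes.sampler.PosteriorDraws` with per-draw deviance and
    the effective proposal-sample size 1/sum(w^2) in ``extra``.
    """
    from .sampler import PosteriorDraws  # deferred: sampler imports laplace types

    if not (n_draws >= n_keep >= 1):
        raise ValueError("need n_draws >= n_keep >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(fit.covariance)
    z = rng.standard_normal((n_draws, fit.mode.size))
    points = fit.mode + z @ L.T
    logq = -0.5 * np.sum(z * z, axis=1)  # N(mode, cov) up to a constant
    logp = np.array([logpost(p) for p in points])
    logw = logp - logq
    finite = np.isfinite(logw)
    if not finite.any():
        raise ApproximationError("all importance weights are zero or non-finite")
    logw = np.where(finite, logw, -np.inf)
    w = np.exp(logw - logw[finite].max())
    w /= w.sum()
    idx = rng.choice(n_draws, size=n_keep, replace=True, p=w)
    draws = points[idx]
    deviance = np.array([logpost.deviance(u) for u in draws])
    layout = getattr(logpost, "layout", None)
    return PosteriorDraws(
        draws=draws,
        names=list(fit.names),
        layout=layout,
        deviance=deviance,
        monitors={},
        acceptance_rate=None,
        thinning=1,
        seed=seed,
        method="sir",
        extra={"ess_proposal": float(1.0 / np.sum(w**2)), "n_draws": int(n_draws)},
    )
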