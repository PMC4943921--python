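"""Exponential power (EP) lifetime distribution.

A two-parameter lifetime model with shape ``gamma`` > 0 and scale
``alpha`` > 0 and density

    f(t) = (gamma / alpha**gamma) * t**(gamma-1) * exp((t/alpha)**gamma)
           * exp(1 - exp((t/alpha)**gamma)),   t >= 0.

Its hazard ``h(t) = (gamma/alpha**gamma) t**(gamma-1) exp((t/alpha)**gamma)``
is monotone increasing for ``gamma >= 1`` and bathtub-shaped for
``0 < gamma < 1``, with minimum at the change-point

    t0 = alpha * ((1 - gamma) / gamma)**(1/gamma).

The CDF is invertible in closed form, which makes inverse-CDF simulation
trivial; this is the same law as ``scipy.stats.exponpow(b=gamma,
scale=alpha)``, re-exposed here with the log-space kernels, hazard
machinery and burn-in/replacement-time solver that the Bayesian fitting
layers need.

All computations go through the log form

    log f = log(gamma) - gamma*log(alpha) + (gamma-1)*log(t)
            + (t/alpha)**gamma + 1 - exp((t/alpha)**gamma)

and exponentiate last; the argument of the outer exponential is clipped
at the double-precision overflow threshold so far-tail evaluations
return an astronomically negative (but finite) log-density instead of
overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EPParams",
    "HazardSolveResult",
    "NoSolutionError",
    "ep_logpdf",
    "ep_pdf",
    "ep_cdf",
    "ep_log_reliability",
    "ep_reliability",
    "ep_hazard",
    "ep_quantile",
    "ep_rng",
    "hazard_changepoint",
    "solve_hazard_times",
]

# exp() overflows IEEE doubles just above this
_EXP_CLIP = 709.0


class NoSolutionError(ValueError):
    """The hazard curve never reaches the requested threshold."""


@dataclass(frozen=True)
class EPParams:
    """Shape ``gamma`` (dimensionless) and scale ``alpha`` (time units)."""

    gamma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"shape gamma must be a positive finite real, got {self.gamma!r}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"scale alpha must be a positive finite real, got {self.alpha!r}")


@dataclass(frozen=True)
class HazardSolveResult:
    """Roots of ``h(t) = threshold``.

    ``lower_root`` is the optimum burn-in time (smallest solution),
    ``upper_root`` the optimum replacement time (largest solution), and
    ``changepoint`` the hazard minimum ``t0`` (present only for the
    bathtub case ``gamma < 1``).
    """

    threshold: float
    lower_root: Optional[float]
    upper_root: Optional[float]
    changepoint: Optional[float]


def _check_times(t, allow_zero: bool = True) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    if not allow_zero and np.any(t == 0):
        raise ValueError("times must be strictly positive")
    return t


def _z(t: np.ndarray, gamma, alpha) -> np.ndarray:
    """(t/alpha)**gamma, safe at t = 0 (returns 0)."""
    with np.errstate(divide="ignore"):
        logt = np.log(t)
    return np.exp(np.clip(gamma * (logt - np.log(alpha)), -np.inf, _EXP_CLIP))


def _logpdf_kernel(t, gamma, alpha):
    """Vectorised over t *and* (gamma, alpha); t must be >= 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log(t)
        z = _z(t, gamma, alpha)
        out = (
            np.log(gamma)
            - gamma * np.log(alpha)
            + (gamma - 1.0) * logt
            + z
            + 1.0
            - np.exp(np.minimum(z, _EXP_CLIP))
        )
    if np.any(t == 0):
        # limits of log f at 0: +inf (gamma<1), log(1/alpha) (gamma=1), -inf (gamma>1)
        gam = np.broadcast_to(np.asarray(gamma, dtype=float), out.shape)
        alp = np.broadcast_to(np.asarray(alpha, dtype=float), out.shape)
        tb = np.broadcast_to(t, out.shape)
        at0 = np.where(gam < 1.0, np.inf, np.where(gam == 1.0, -np.log(alp), -np.inf))
        out = np.where(tb == 0, at0, out)
    return out


def ep_logpdf(t, params: EPParams):
    """Log-density of the EP distribution; the form used by all likelihoods."""
    t = _check_times(t)
    return _logpdf_kernel(t, params.gamma, params.alpha)


def ep_pdf(t, params: EPParams):
    """Density f(t).  At t = 0 this is 1/alpha for gamma = 1, 0 for
    gamma > 1 and +inf for gamma < 1 (the hazard pole of the bathtub)."""
    return np.exp(ep_logpdf(t, params))


def _log_reliability_kernel(t, gamma, alpha):
    z = _z(np.asarray(t, dtype=float), gamma, alpha)
    return -np.expm1(np.minimum(z, _EXP_CLIP))  # 1 - exp(z)


def ep_log_reliability(t, params: EPParams):
    """log R(t) = 1 - exp((t/alpha)**gamma)."""
    t = _check_times(t)
    return _log_reliability_kernel(t, params.gamma, params.alpha)


def ep_reliability(t, params: EPParams):
    """Survival probability R(t) = exp[1 - exp((t/alpha)**gamma)]."""
    return np.exp(ep_log_reliability(t, params))


def ep_cdf(t, params: EPParams):
    """F(t) = 1 - R(t), computed as -expm1(log R) for accuracy near 0."""
    return -np.expm1(ep_log_reliability(t, params))


def _hazard_kernel(t, gamma, alpha):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log(t)
        z = _z(t, gamma, alpha)
        logh = np.log(gamma) - gamma * np.log(alpha) + (gamma - 1.0) * logt + z
        out = np.exp(np.minimum(logh, _EXP_CLIP))
    if np.any(t == 0):
        gam = np.broadcast_to(np.asarray(gamma, dtype=float), out.shape)
        alp = np.broadcast_to(np.asarray(alpha, dtype=float), out.shape)
        tb = np.broadcast_to(t, out.shape)
        at0 = np.where(gam < 1.0, np.inf, np.where(gam == 1.0, 1.0 / alp, 0.0))
        out = np.where(tb == 0, at0, out)
    return out


def ep_hazard(t, params: EPParams):
    """Failure rate h(t) = f(t)/R(t); diverges at 0 when gamma < 1."""
    t = _check_times(t)
    return _hazard_kernel(t, params.gamma, params.alpha)


def ep_quantile(u, params: EPParams):
    """Inverse CDF: t = alpha * [log(1 - log(1 - u))]**(1/gamma), 0 <= u < 1."""
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(u < 0) or np.any(u >= 1):
        raise ValueError("probabilities must lie in [0, 1)")
    inner = np.log1p(-np.log1p(-u))
    return params.alpha * inner ** (1.0 / params.gamma)


def ep_rng(n: int, params: EPParams, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. EP lifetimes by the inverse-CDF transform.

    ``seed`` is mandatory (an int, SeedSequence or Generator); identical
    seeds give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return ep_quantile(rng.random(int(n)), params)


def hazard_changepoint(params: EPParams) -> Optional[float]:
    """Hazard minimum t0 = alpha*((1-gamma)/gamma)**(1/gamma) for
    gamma < 1; ``None`` when gamma >= 1 (monotone hazard)."""
    g = params.gamma
    if g >= 1.0:
        return None
    return params.alpha * ((1.0 - g) / g) ** (1.0 / g)


def solve_hazard_times(
    threshold: float, params: EPParams, tol: float = 1e-12
) -> HazardSolveResult:
    """Solve ``h(t) = threshold`` for burn-in and replacement times.

    For the bathtub case (gamma < 1) there are two solutions whenever the
    threshold exceeds the hazard minimum h(t0): the smallest is the
    optimum burn-in time, the largest the optimum replacement time.  For
    gamma >= 1 the hazard is monotone increasing and at most one root
    exists; it is returned as ``upper_root``.

    Brent's method on a bracketed interval, with geometric (factor 2)
    bracket expansion above t0 until the hazard exceeds the threshold.
    """
    if not (np.isfinite(threshold) and threshold > 0):
        raise ValueError("threshold must be a positive finite rate")
    g, a = params.gamma, params.alpha

    def h(t):
        return float(_hazard_kernel(t, g, a))

    def expand_up(lo: float) -> float:
        hi = max(2.0 * lo, a)
        while h(hi) < threshold:
            hi *= 2.0
            if hi > 1e30:  # pragma: no cover - unreachable for valid params
                raise NoSolutionError("hazard never reaches the threshold")
        return hi

    if g >= 1.0:
        h0 = 1.0 / a if g == 1.0 else 0.0
        if threshold <= h0:
            raise NoSolutionError(
                f"threshold {threshold} is not above the minimum hazard {h0}"
            )
        hi = expand_up(a * 1e-12)
        root = brentq(lambda t: h(t) - threshold, 0.0, hi, xtol=tol, rtol=1e-15)
        return HazardSolveResult(threshold, None, float(root), None)

    t0 = hazard_changepoint(params)
    hmin = h(t0)
    if threshold < hmin:
        raise NoSolutionError(
            f"threshold {threshold} is below the hazard minimum h(t0) = {hmin}"
        )
    if threshold == hmin:
        return HazardSolveResult(threshold, float(t0), float(t0), float(t0))
    # lower bracket: shrink towards 0 until the hazard pole dominates
    lo = t0 / 2.0
    while h(lo) < threshold:
        lo /= 2.0
    lower = brentq(lambda t: h(t) - threshold, lo, t0, xtol=tol, rtol=1e-15)
    upper = brentq(lambda t: h(t) - threshold, t0, expand_up(t0), xtol=tol, rtol=1e-15)
    return HazardSolveResult(threshold, float(lower), float(upper), float(t0))
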