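"""scikit-learn style front end for the Bayesian EP lifetime model.

``ExponentialPowerFitter`` composes the posterior, Laplace and sampling
layers behind a familiar ``fit``/``predict`` surface so the model can sit
inside sklearn pipelines and model-selection utilities; the underlying
functional API (:mod:`epbayes.laplace`, :mod:`epbayes.sampler`) remains
the primary library surface for survival-specific work.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import LifetimeSample
from .distribution import EPParams, _hazard_kernel, ep_quantile
from .laplace import laplace_approximation, sir_resample
from .posterior import LogPosterior, PriorSpec, RegressionParams
from .sampler import run_im_chain, summarize_chain

__all__ = ["ExponentialPowerFitter"]

_MEDIAN_CONST = math.log(1.0 - math.log(0.5))  # log(1 - log(1-u)) at u = 1/2; median = alpha * c**(1/gamma)


def _coerce_y(y) -> tuple:
    """Accept times, an (n, 2) [time, status] array, a structured array
    with time/event fields, or a DataFrame with 'time'/'status'."""
    if isinstance(y, pd.DataFrame):
        status = y["status"] if "status" in y else y.get("event")
        return np.asarray(y["time"], dtype=float), (
            None if status is None else np.asarray(status, dtype=int)
        )
    y = np.asarray(y)
    if y.dtype.names:  # structured, scikit-survival style (event first or named)
        names = y.dtype.names
        tname = next(n for n in names if "time" in n.lower())
        ename = next(n for n in names if n != tname)
        return y[tname].astype(float), y[ename].astype(int)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    return y.astype(float).ravel(), None


class ExponentialPowerFitter(BaseEstimator):
    """Bayesian exponential power lifetime model.

    Parameters
    ----------
    method : {"im", "sir", "laplace"}
        Posterior machinery: independence Metropolis seeded by the
        Laplace fit (default), sampling importance resampling from the
        Laplace fit, or the Gaussian Laplace approximation alone.
    acceptance_rule : {"exact", "reference"}
        IM acceptance rule; see :func:`epbayes.sampler.run_im_chain`.
    hc_scale, beta_location, beta_scale :
        Prior hyperparameters (half-Cauchy scale for positive
        parameters; normal moments for regression coefficients).
    optimizer : {"nelder-mead", "bfgs"}
        Mode-finding algorithm for the Laplace step.
    tol, max_iter :
        Optimizer stopping tolerance and iteration cap.
    iterations, thinning :
        IM chain length and thinning interval (S_kept = iterations //
        thinning).
    n_draws, n_keep :
        SIR proposal draws and resample size.
    proposal_scale :
        Multiplier on the proposal standard deviations.
    random_state :
        Seed for every stochastic step.

    Attributes
    ----------
    laplace_ : LaplaceFit
    draws_ : PosteriorDraws or None
    summary_ : DataFrame of posterior summaries
    params_ : EPParams or RegressionParams at the posterior mean
        (natural scale; mode-based when ``method="laplace"``).
    """

    def __init__(
        self,
        method: str = "im",
        acceptance_rule: str = "exact",
        hc_scale: float = 25.0,
        beta_location: float = 0.0,
        beta_scale: float = math.sqrt(1000.0),
        optimizer: str = "nelder-mead",
        tol: float = 1e-5,
        max_iter: int = 2000,
        iterations: int = 10000,
        thinning: int = 10,
        n_draws: int = 10000,
        n_keep: int = 1000,
        proposal_scale: float = 1.0,
        random_state: Optional[int] = 0,
    ) -> None:
        self.method = method
        self.acceptance_rule = acceptance_rule
        self.hc_scale = hc_scale
        self.beta_location = beta_location
        self.beta_scale = beta_scale
        self.optimizer = optimizer
        self.tol = tol
        self.max_iter = max_iter
        self.iterations = iterations
        self.thinning = thinning
        self.n_draws = n_draws
        self.n_keep = n_keep
        self.proposal_scale = proposal_scale
        self.random_state = random_state

    # -- fitting ------------------------------------------------------

    def fit(self, X, y):
        """Fit the model.

        ``X`` holds covariates (n x J) and selects the regression model;
        pass ``None`` (or an empty array) for the no-covariate model.
        ``y`` holds the lifetimes, optionally with 0/1 censoring
        statuses (second column, structured field, or 'status' column).
        """
        if self.method not in ("im", "sir", "laplace"):
            raise ValueError("method must be 'im', 'sir' or 'laplace'")
        times, status = _coerce_y(y)
        cov = None
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.size:
                cov = X.reshape(len(times), -1)
        sample = LifetimeSample(times, status, cov)
        prior = PriorSpec(self.hc_scale, self.beta_location, self.beta_scale)
        logpost = LogPosterior(sample, prior)
        self.log_posterior_ = logpost
        self.laplace_ = laplace_approximation(
            logpost, method=self.optimizer, tol=self.tol, max_iter=self.max_iter
        )
        if self.method == "im":
            self.draws_ = run_im_chain(
                logpost,
                self.laplace_,
                iterations=self.iterations,
                thinning=self.thinning,
                seed=self.random_state,
                proposal_scale=self.proposal_scale,
                acceptance_rule=self.acceptance_rule,
            )
        elif self.method == "sir":
            self.draws_ = sir_resample(
                logpost, self.laplace_, n_draws=self.n_draws,
                n_keep=self.n_keep, seed=self.random_state,
            )
        else:
            self.draws_ = None
        if self.draws_ is not None:
            self.summary_ = summarize_chain(self.draws_)
            nat = self.draws_.natural()
            if logpost.kind == "null":
                self.params_ = EPParams(float(nat["gamma"].mean()),
                                        float(nat["alpha"].mean()))
            else:
                self.params_ = RegressionParams(
                    float(nat["gamma"].mean()), nat["beta"].mean(axis=0)
                )
        else:
            self.summary_ = self.laplace_.summary()
            u = self.laplace_.mode
            self.params_ = logpost.layout.to_natural(u)
            if logpost.kind == "null":
                self.params_ = EPParams(math.exp(u[0]), math.exp(u[1]))
        self.n_features_in_ = 0 if cov is None else cov.shape[1]
        return self

    # -- prediction ---------------------------------------------------

    def _scales(self, X) -> np.ndarray:
        p = self.params_
        if isinstance(p, EPParams):
            n = 1 if X is None else len(np.atleast_2d(X))
            return np.full(n, p.alpha)
        if X is None:
            raise ValueError("the regression model needs covariates to predict")
        X = np.asarray(X, dtype=float).reshape(-1, self.n_features_in_)
        return np.exp(p.beta[0] + X @ p.beta[1:])

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean-parameter median lifetime for each row of X
        (a single value for the no-covariate model)."""
        check_is_fitted(self, "params_")
        return self._scales(X) * _MEDIAN_CONST ** (1.0 / self.params_.gamma)

    def predict_quantile(self, q: float, X=None) -> np.ndarray:
        check_is_fitted(self, "params_")
        scales = self._scales(X)
        return scales * ep_quantile(q, EPParams(self.params_.gamma, 1.0))

    def hazard(self, t, X=None) -> np.ndarray:
        """Failure rate at times t under the posterior-mean parameters."""
        check_is_fitted(self, "params_")
        scales = self._scales(X)
        if scales.size == 1:
            return _hazard_kernel(np.asarray(t, float), self.params_.gamma, scales[0])
        return _hazard_kernel(np.asarray(t, float), self.params_.gamma, scales)

    def reliability(self, t, X=None) -> np.ndarray:
        """Survival probability at times t under the posterior-mean
        parameters."""
        check_is_fitted(self, "params_")
        scales = self._scales(X)
        a = scales[0] if scales.size == 1 else scales
        z = (np.asarray(t, float) / a) ** self.params_.gamma
        return np.exp(1.0 - np.exp(np.minimum(z, 709.0)))

    def posterior_summary(self) -> pd.DataFrame:
        check_is_fitted(self, "summary_")
        return self.summary_
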