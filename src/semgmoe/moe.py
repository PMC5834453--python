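"""Scikit-learn style estimator for the Bayesian mixture of experts.

:class:`BayesianMixtureOfExperts` fits the multivariate mixture of linear
experts by variational Bayes EM with automatic expert pruning and ARD, over
multiple random restarts, keeping the restart with the largest evidence
lower bound. ``predict`` returns the winner-takes-all predictive mean;
``predict_dist`` exposes the full Student-t predictive distribution and
``predict_expert`` the gate-based (unsupervised) movement classification.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _vb, predictive

logger = logging.getLogger(__name__)

__all__ = ["BayesianMixtureOfExperts"]


class BayesianMixtureOfExperts(BaseEstimator, RegressorMixin):
    """Mixture of linear experts with normalized-Gaussian gates, VB-trained.

    Parameters
    ----------
    n_experts : initial expert count; surplus experts are pruned when their
        mixing weight falls below ``prune_threshold`` (default 1/(2N)).
    n_restarts : independent VBEM runs with random responsibilities and
        K-means gate prior means; the run with the largest final lower
        bound is kept.
    max_iter, tol : per-run stopping rule on the relative bound change.
    beta0, nu0, c0, d0 : Gaussian-Wishart / Gamma prior hyperparameters
        (B0 = I, Q0 = I, lambda0 = d_y, nu0 defaults to d_x); the defaults
        define broad priors appropriate for standardized features.
    random_state : seed controlling every source of randomness.

    Attributes
    ----------
    gates_, experts_, ard_ : variational posterior families of the winner.
    weights_ : mixing coefficients over the surviving experts.
    n_experts_ : surviving expert count.
    lower_bound_, lower_bound_trace_ : final bound and per-pass trace.
    converged_ : whether the best run met the tolerance.
    """

    def __init__(
        self,
        n_experts: int = 10,
        n_restarts: int = 100,
        max_iter: int = 200,
        tol: float = 1e-6,
        prune_threshold: float | None = None,
        beta0: float = 0.01,
        nu0: float | None = None,
        lambda0: float | None = None,
        c0: float = 0.01,
        d0: float = 0.0001,
        random_state: int | None = None,
    ):
        self.n_experts = n_experts
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.prune_threshold = prune_threshold
        self.beta0 = beta0
        self.nu0 = nu0
        self.lambda0 = lambda0
        self.c0 = c0
        self.d0 = d0
        self.random_state = random_state

    def _validate_xy(self, X, Y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if Y is None:
            return X
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if len(X) != len(Y):
            raise ValueError("X and Y must have the same number of rows")
        if not np.isfinite(Y).all():
            raise ValueError("Y contains non-finite values")
        return X, Y

    def fit(self, X, y):
        """Fit by multi-restart VBEM; keeps the largest-lower-bound run."""
        X, Y = self._validate_xy(X, y)
        hyper = _vb.Hyperparameters(
            d_x=X.shape[1], d_y=Y.shape[1], beta0=self.beta0, nu0=self.nu0,
            lambda0=self.lambda0, c0=self.c0, d0=self.d0)
        best = None
        for s in range(self.n_restarts):
            seed = (None if self.random_state is None
                    else np.random.default_rng([self.random_state, s]))
            state = _vb.fit_single(
                X, Y, hyper, M_init=self.n_experts, max_iter=self.max_iter,
                tol=self.tol, prune_threshold=self.prune_threshold, seed=seed)
            logger.info("restart %d: bound %.4f, %d experts, converged=%s",
                        s, state.lower_bound, state.n_experts, state.converged)
            if best is None or state.lower_bound > best.lower_bound:
                best = state
        if not best.converged:
            logger.warning("no restart reached the convergence tolerance")
        self.gates_ = best.gates
        self.experts_ = best.experts
        self.ard_ = best.ard
        self.weights_ = best.pi
        self.responsibilities_ = best.r
        self.hyper_ = best.hyper
        self.lower_bound_trace_ = np.asarray(best.lower_bound_trace)
        self.lower_bound_ = best.lower_bound
        self.converged_ = best.converged
        self.n_experts_ = best.n_experts
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = Y.shape[1]
        return self

    def predict(self, X):
        """Winner-takes-all predictive mean, shape (n, d_y)."""
        check_is_fitted(self, "gates_")
        X = self._validate_xy(X)
        means, _, _ = predictive.predict_sequence(X, self, with_cov=False)
        return means

    def predict_dist(self, X):
        """Full per-row Student-t predictive distributions (list)."""
        check_is_fitted(self, "gates_")
        X = self._validate_xy(X)
        return [predictive.predictive(x, self) for x in X]

    def predict_expert(self, X):
        """Gate-based expert (movement cluster) index per row."""
        check_is_fitted(self, "gates_")
        X = self._validate_xy(X)
        return predictive.classify(X, self)

    def gate_probabilities(self, X):
        """Normalized-Gaussian gate probabilities at MAP estimates, (n, M)."""
        check_is_fitted(self, "gates_")
        X = self._validate_xy(X)
        return predictive.gate_probabilities(X, self)
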