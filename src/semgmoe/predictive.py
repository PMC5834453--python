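"""Posterior predictive distribution and gate-based classification.

Predictions are winner-takes-all: the gate with the largest normalized-
Gaussian probability (evaluated at MAP gate estimates) selects the expert,
and the force prediction is that expert's multivariate Student-t posterior
predictive with kappa = lambda - d_y + 1 degrees of freedom, mean
[x 1] What, scale Q^-1 (1 + [x 1] L [x 1]') / kappa and hence covariance
Q^-1 (1 + [x 1] L [x 1]') / (kappa - 2) when kappa > 2. Extrapolating
inputs inflate the (1 + [x 1] L [x 1]') factor, so the uncertainty grows
away from the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import t as student_t

__all__ = [
    "PredictiveDistribution",
    "gate_log_probabilities",
    "gate_probabilities",
    "classify",
    "predictive",
    "predict_sequence",
    "confidence_interval",
]


@dataclass
class PredictiveDistribution:
    """Winning-expert Student-t predictive at one query point.

    ``scale`` is the Student-t scale matrix, so the covariance equals
    scale * dof / (dof - 2); ``covariance`` is None when dof <= 2
    (undefined).
    """

    winner: int
    mean: np.ndarray
    dof: float
    scale: np.ndarray
    covariance: np.ndarray | None
    gate_probs: np.ndarray


def gate_log_probabilities(X: np.ndarray, model) -> np.ndarray:
    """Log gate probabilities ln g_i(x) at MAP gate estimates, (n, M).

    g_i(x) is proportional to pi_i N(x | m_i, Lambda_MAP_i^-1) with
    Lambda_MAP_i = nu_i B_i (the Wishart posterior mean, defined for every
    valid posterior), normalized over experts in log space.
    """
    gates = model.gates_
    pi = model.weights_
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d_x = X.shape
    M = gates.n_experts
    log_dens = np.empty((n, M))
    for i in range(M):
        Lam = gates.nu[i] * gates.B[i]
        _, logdet = np.linalg.slogdet(Lam)
        diff = X - gates.m[i]
        quad = np.einsum("nj,jk,nk->n", diff, Lam, diff)
        log_dens[:, i] = 0.5 * (logdet - d_x * np.log(2 * np.pi) - quad)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    log_g = log_pi[None, :] + log_dens
    return log_g - logsumexp(log_g, axis=1, keepdims=True)


def gate_probabilities(X: np.ndarray, model) -> np.ndarray:
    """Normalized gate probabilities per row, rows sum to 1."""
    return np.exp(gate_log_probabilities(X, model))


def classify(X: np.ndarray, model) -> np.ndarray:
    """Index of the dominant expert per row (ties -> lowest index)."""
    out = np.argmax(gate_log_probabilities(X, model), axis=1)
    return out if np.ndim(X) > 1 else int(out[0])


def predictive(x: np.ndarray, model) -> PredictiveDistribution:
    """Student-t posterior predictive of the winning expert at one point."""
    x = np.asarray(x, dtype=float).ravel()
    log_g = gate_log_probabilities(x[None, :], model)[0]
    winner = int(np.argmax(log_g))
    ex = model.experts_
    xt = np.append(x, 1.0)
    mean = xt @ ex.W_hat[winner]
    kappa = float(ex.lam[winner]) - mean.shape[0] + 1.0
    Q_inv = np.linalg.inv(ex.Q[winner])
    infl = 1.0 + xt @ ex.L[winner] @ xt
    scale = Q_inv * infl / kappa
    cov = Q_inv * infl / (kappa - 2.0) if kappa > 2 else None
    return PredictiveDistribution(winner=winner, mean=mean, dof=kappa,
                                  scale=0.5 * (scale + scale.T),
                                  covariance=None if cov is None else 0.5 * (cov + cov.T),
                                  gate_probs=np.exp(log_g))


def predict_sequence(
    X: np.ndarray, model, with_cov: bool = True
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Vectorized winner-takes-all prediction over a session.

    Returns (means, covariances, winners); covariances is None when
    ``with_cov`` is False, and rows with dof <= 2 carry NaN covariance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    winners = np.argmax(gate_log_probabilities(X, model), axis=1)
    ex = model.experts_
    n = len(X)
    d_y = ex.W_hat.shape[2]
    Xt = np.column_stack([X, np.ones(n)])
    means = np.empty((n, d_y))
    covs = np.full((n, d_y, d_y), np.nan) if with_cov else None
    for i in np.unique(winners):
        sel = winners == i
        means[sel] = Xt[sel] @ ex.W_hat[i]
        if with_cov:
            kappa = float(ex.lam[i]) - d_y + 1.0
            if kappa > 2:
                Q_inv = np.linalg.inv(ex.Q[i])
                infl = 1.0 + np.einsum("nj,jk,nk->n", Xt[sel], ex.L[i], Xt[sel])
                covs[sel] = Q_inv[None] * (infl / (kappa - 2.0))[:, None, None]
    return means, covs, winners


def confidence_interval(
    pred: PredictiveDistribution, level: float = 0.99
) -> tuple[np.ndarray, np.ndarray]:
    """Per-DoF marginal Student-t interval (lower, upper) around the mean."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    half = student_t.ppf(0.5 * (1 + level), df=pred.dof) * np.sqrt(np.diag(pred.scale))
    return pred.mean - half, pred.mean + half
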