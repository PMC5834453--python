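"""Regression-based global sensitivity analysis for correlated inputs.

Quantifies how much of the model's output force variance each sEMG input
(or group of electrodes) accounts for, decomposing each first-order share
S_j into an uncorrelated part SU_j (unique to input j, from the residual
of x_j after regressing on all other inputs) and a correlated part
SC_j = S_j - SU_j (carried through correlations with the other inputs).
A spurious electrode shows a near-zero SU with a large SC: it only moves
the output through its correlation with genuinely informative electrodes.

Samples are drawn by Latin hypercube sampling from the empirical marginals
of the training features, with the Iman-Conover rank-shuffle inducing the
target Spearman correlation structure so the sample respects the observed
inter-electrode correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, rankdata, spearmanr

__all__ = [
    "SensitivityIndices",
    "iman_conover_lhs",
    "total_variance",
    "sensitivity_indices",
    "electrode_groups",
]


@dataclass
class SensitivityIndices:
    """First-order variance shares per input (or group) and output DoF.

    S, SU, SC have shape (n_inputs_or_groups, d_y); S = SU + SC by
    construction. V is the total output variance per DoF.
    """

    S: np.ndarray
    SU: np.ndarray
    SC: np.ndarray
    V: np.ndarray
    n_samples: int
    groups: list[list[int]] | None = None


def _check_rank_corr(rank_corr: np.ndarray) -> np.ndarray:
    C = np.asarray(rank_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("rank_corr must be square")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("rank_corr must be symmetric with unit diagonal")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "rank_corr is not positive definite; repair it with a "
            "nearest-correlation-matrix projection before sampling"
        ) from exc
    return C


def iman_conover_lhs(
    marginals: np.ndarray,
    rank_corr: np.ndarray | None = None,
    n_samples: int = 2000,
    seed: int | None = None,
) -> np.ndarray:
    """Rank-correlated Latin hypercube sample from empirical marginals.

    Each column is a stratified draw from the empirical quantile function
    of the corresponding column of ``marginals`` (one draw per equiprobable
    stratum), then the columns are reordered by the Iman-Conover procedure
    (van der Waerden scores, Cholesky transform, rank matching) so the
    realized Spearman matrix approximates ``rank_corr`` while the marginals
    are untouched. ``rank_corr=None`` targets independence.
    """
    data = np.atleast_2d(np.asarray(marginals, dtype=float))
    d = data.shape[1]
    if rank_corr is None:
        rank_corr = np.eye(d)
    C = _check_rank_corr(rank_corr)
    if C.shape[0] != d:
        raise ValueError("rank_corr dimension must match the number of inputs")
    rng = np.random.default_rng(seed)

    # stratified marginal draws: one point per equiprobable stratum
    u = (np.arange(n_samples)[:, None] + rng.uniform(size=(n_samples, d))) / n_samples
    for j in range(d):
        rng.shuffle(u[:, j])
    lhs = np.column_stack(
        [np.quantile(data[:, j], u[:, j]) for j in range(d)])

    # Iman-Conover rank shuffle toward the target rank correlation
    scores = norm.ppf(np.arange(1, n_samples + 1) / (n_samples + 1))
    S = np.column_stack([rng.permutation(scores) for _ in range(d)])
    E = np.corrcoef(S, rowvar=False)
    F = np.linalg.cholesky(E)
    P = np.linalg.cholesky(C)
    T = S @ np.linalg.inv(F).T @ P.T
    out = np.empty_like(lhs)
    for j in range(d):
        ranks = rankdata(T[:, j], method="ordinal").astype(int) - 1
        out[:, j] = np.sort(lhs[:, j])[ranks]
    return out


def total_variance(y_samples: np.ndarray) -> np.ndarray:
    """Population variance of the sampled outputs per DoF."""
    y = np.atleast_2d(np.asarray(y_samples, dtype=float).T).T
    if len(y) < 2:
        raise ValueError("need at least two samples")
    return np.mean((y - y.mean(axis=0)) ** 2, axis=0)


def _fitted_variance(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Variance of OLS fitted values of y on [1, design], per output DoF."""
    A = np.column_stack([np.ones(len(design)), design])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    return np.mean((fitted - fitted.mean(axis=0)) ** 2, axis=0)


def _residualize(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Residual of target columns after OLS on [1, others]."""
    A = np.column_stack([np.ones(len(others)), others])
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    return target - A @ coef


def sensitivity_indices(
    model_predict: Callable[[np.ndarray], np.ndarray],
    marginals: np.ndarray,
    rank_corr: np.ndarray | None = None,
    groups: Sequence[Sequence[int]] | None = None,
    n_samples: int = 2000,
    seed: int | None = None,
) -> SensitivityIndices:
    """Estimate first-order S/SU/SC variance shares via regression-based SA.

    ``model_predict`` maps an (n, d_x) sample matrix to (n,) or (n, d_y)
    outputs (typically the predictive mean of a fitted mixture).
    ``marginals`` is training feature data supplying empirical marginals;
    when ``rank_corr`` is None the Spearman correlation of ``marginals``
    is used as the target, so the sample mimics the training distribution.

    For each input j: V_j is the variance of the OLS fit of y on x_j alone;
    VU_j is the variance of the OLS fit of y on the residual of x_j after
    regressing x_j on all other inputs; VC_j = V_j - VU_j. Groups are
    handled identically with the group's columns as a multivariate block.
    """
    data = np.atleast_2d(np.asarray(marginals, dtype=float))
    d = data.shape[1]
    if rank_corr is None:
        if d > 1:
            rho = spearmanr(data).statistic
            if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case
                rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
            rank_corr = np.atleast_2d(rho)
            # guard: empirical Spearman can be numerically semidefinite
            w, V = np.linalg.eigh((rank_corr + rank_corr.T) / 2)
            rank_corr = (V * np.maximum(w, 1e-10)) @ V.T
            dd = np.sqrt(np.diag(rank_corr))
            rank_corr = rank_corr / np.outer(dd, dd)
        else:
            rank_corr = np.eye(1)

    if groups is None:
        blocks = [[j] for j in range(d)]
        groups_out = None
    else:
        blocks = [list(g) for g in groups]
        flat = sorted(j for g in blocks for j in g)
        if len(flat) != len(set(flat)):
            raise ValueError("groups must not overlap")
        if flat != list(range(d)):
            raise ValueError("groups must partition all inputs")
        groups_out = blocks

    X = iman_conover_lhs(data, rank_corr, n_samples=n_samples, seed=seed)
    y = np.asarray(model_predict(X), dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    V = total_variance(y)
    if np.any(V == 0):
        raise ValueError("model output has zero variance; indices undefined")

    S = np.empty((len(blocks), y.shape[1]))
    SU = np.empty_like(S)
    for k, block in enumerate(blocks):
        xb = X[:, block]
        others = np.delete(X, block, axis=1)
        S[k] = _fitted_variance(y, xb) / V
        if others.shape[1] == 0:
            SU[k] = S[k]
        else:
            zb = _residualize(xb, others)
            SU[k] = _fitted_variance(y, zb) / V
    return SensitivityIndices(S=S, SU=SU, SC=S - SU, V=V,
                              n_samples=n_samples, groups=groups_out)


def electrode_groups(
    n_channels: int = 12, layout: Sequence[Sequence[int]] | None = None
) -> list[list[int]]:
    """Electrode grouping by anatomical location (0-based channel indices).

    The default 12-channel layout groups channels 1-8 (forearm ring), 9-10
    (finger extensor and flexor) and 11-12 (upper arm: biceps and triceps),
    i.e. 0-based [0..7], [8, 9], [10, 11]. A custom ``layout`` is accepted
    when it partitions all channels without overlap.
    """
    if layout is None:
        if n_channels < 12:
            raise ValueError("default layout requires at least 12 channels")
        layout = [list(range(8)), [8, 9], [10, 11]]
        if n_channels > 12:
            layout.append(list(range(12, n_channels)))
    blocks = [list(g) for g in layout]
    flat = sorted(j for g in blocks for j in g)
    if len(flat) != len(set(flat)):
        raise ValueError("electrode groups must not overlap")
    if flat != list(range(n_channels)):
        raise ValueError("electrode groups must cover every channel exactly once")
    return blocks
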