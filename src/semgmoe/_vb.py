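"""Variational Bayes EM updates for the multivariate mixture of experts.

The model: each data point (x_n, y_n) belongs to one of M experts. Expert i
owns a Gaussian gate component N(x | mu_i, Lambda_i^-1) with mixing weight
pi_i, and a linear-Gaussian regression y = W_i'[x;1] + e, e ~ N(0, chi_i^-1).
Conjugate priors: Gaussian-Wishart on (mu_i, Lambda_i), matrix-Normal-Wishart
on (W_i, chi_i) with per-input ARD precisions a_ij ~ Gamma(c0, d0). The
mixing weights are point-estimated.

The VBM step updates the closed-form variational posteriors (Gaussian-
Wishart gates, matrix-Normal-Wishart experts, Gamma ARD); the VBE step
updates the responsibilities in log space. Mixing weights are re-estimated
each pass and experts whose weight falls below a threshold are pruned,
which performs automatic model-order selection. Every pass maximizes the
evidence lower bound computed by :func:`lower_bound`, so the bound trace is
non-decreasing; restarts are compared by their final bound.

All Wishart distributions use the scale parameterization W(Lambda | B, nu)
with E[Lambda] = nu * B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln, logsumexp, multigammaln
from sklearn.cluster import KMeans

_EMPTY = 1e-10  # an expert with total responsibility below this keeps its prior

__all__ = [
    "Hyperparameters",
    "GatePosterior",
    "ExpertPosterior",
    "ARDPosterior",
    "init_state",
    "vbm_gates",
    "vbm_experts",
    "vbm_ard",
    "vbe_step",
    "update_mixing",
    "prune_experts",
    "lower_bound",
    "fit_single",
]


@dataclass
class Hyperparameters:
    """Prior hyperparameters; defaults define broad priors on standardized data."""

    d_x: int
    d_y: int
    beta0: float = 0.01
    B0: np.ndarray | None = None
    nu0: float | None = None
    Q0: np.ndarray | None = None
    lambda0: float | None = None
    c0: float = 0.01
    d0: float = 0.0001
    m0: np.ndarray | None = None  # (M, d_x), set per restart from K-means

    def __post_init__(self) -> None:
        if self.B0 is None:
            self.B0 = np.eye(self.d_x)
        if self.nu0 is None:
            self.nu0 = float(self.d_x)
        if self.Q0 is None:
            self.Q0 = np.eye(self.d_y)
        if self.lambda0 is None:
            self.lambda0 = float(self.d_y)
        if self.nu0 <= self.d_x - 1:
            raise ValueError("nu0 must exceed d_x - 1")
        if self.lambda0 < self.d_y:
            raise ValueError("lambda0 must be >= d_y")
        if min(self.beta0, self.c0, self.d0) <= 0:
            raise ValueError("beta0, c0 and d0 must be positive")

    def subset(self, keep: np.ndarray) -> "Hyperparameters":
        h = Hyperparameters(self.d_x, self.d_y, self.beta0, self.B0, self.nu0,
                            self.Q0, self.lambda0, self.c0, self.d0)
        h.m0 = None if self.m0 is None else self.m0[keep]
        return h


@dataclass
class GatePosterior:
    """Gaussian-Wishart q(mu_i, Lambda_i) = N(mu|m, (beta Lambda)^-1) W(Lambda|B, nu)."""

    m: np.ndarray      # (M, d_x)
    beta: np.ndarray   # (M,)
    B: np.ndarray      # (M, d_x, d_x)
    nu: np.ndarray     # (M,)

    @property
    def n_experts(self) -> int:
        return len(self.beta)

    def subset(self, keep):
        return GatePosterior(self.m[keep], self.beta[keep], self.B[keep], self.nu[keep])


@dataclass
class ExpertPosterior:
    """Matrix-Normal-Wishart q(W_i, chi_i) = MN(W|What, L, chi^-1) W(chi|Q, lam)."""

    W_hat: np.ndarray  # (M, d_x+1, d_y)
    L: np.ndarray      # (M, d_x+1, d_x+1)
    lam: np.ndarray    # (M,)
    Q: np.ndarray      # (M, d_y, d_y)

    @property
    def n_experts(self) -> int:
        return len(self.lam)

    def subset(self, keep):
        return ExpertPosterior(self.W_hat[keep], self.L[keep], self.lam[keep], self.Q[keep])


@dataclass
class ARDPosterior:
    """Gamma q(a_ij) = Ga(c_i, d_ij); E[a_ij] = c_i / d_ij."""

    c: np.ndarray  # (M,)
    d: np.ndarray  # (M, d_x+1)

    @property
    def Upsilon(self) -> np.ndarray:
        """Posterior-mean ARD precisions diag entries, (M, d_x+1)."""
        return self.c[:, None] / self.d

    def subset(self, keep):
        return ARDPosterior(self.c[keep], self.d[keep])


def _spd_inverse(A: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of an SPD matrix, with one jitter retry."""
    A = 0.5 * (A + A.T)
    for jitter in (0.0, 1e-10 * np.trace(A) / len(A) + 1e-12):
        try:
            c, low = cho_factor(A + jitter * np.eye(len(A)))
            inv = cho_solve((c, low), np.eye(len(A)))
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            return 0.5 * (inv + inv.T), logdet
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(f"{what} is not positive definite even after jitter")


def init_state(
    X: np.ndarray,
    Y: np.ndarray,
    hyper: Hyperparameters,
    M_init: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Hyperparameters]:
    """Random-responsibility initialization with K-means gate prior means.

    Returns (responsibilities, Upsilon, pi, hyper-with-m0). Responsibilities
    are U[0,1] draws row-normalized; Upsilon starts at its prior mean
    (c0/d0) I; pi is uniform; m0 holds the K-means centroids of X.
    """
    N = len(X)
    if N < M_init:
        raise ValueError(f"need at least M_init={M_init} samples, got {N}")
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(size=(N, M_init))
    r = gamma / gamma.sum(axis=1, keepdims=True)
    Upsilon = np.full((M_init, hyper.d_x + 1), hyper.c0 / hyper.d0)
    pi = np.full(M_init, 1.0 / M_init)
    km_seed = int(rng.integers(2**31 - 1))
    if M_init == 1:
        m0 = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=M_init, n_init=10, random_state=km_seed).fit(X)
        m0 = km.cluster_centers_
    h = hyper.subset(np.arange(M_init))
    h.m0 = np.asarray(m0, dtype=float)
    return r, Upsilon, pi, h


def vbm_gates(X: np.ndarray, r: np.ndarray, hyper: Hyperparameters) -> GatePosterior:
    """Gaussian-Wishart gate updates.

    N_i = sum_n r_ni; beta_i = beta0 + N_i; m_i = (beta0 m0 + sum r_ni x_n)/beta_i;
    nu_i = nu0 + N_i; B_i^-1 = B0^-1 + sum r_ni x_n x_n' + beta0 m0 m0'
    - beta_i m_i m_i'.
    """
    M = r.shape[1]
    d_x = X.shape[1]
    m0 = hyper.m0 if hyper.m0 is not None else np.zeros((M, d_x))
    Nk = r.sum(axis=0)
    beta = hyper.beta0 + Nk
    m = (hyper.beta0 * m0 + r.T @ X) / beta[:, None]
    nu = hyper.nu0 + Nk
    B0_inv, _ = _spd_inverse(hyper.B0, "B0")
    B = np.empty((M, d_x, d_x))
    for i in range(M):
        if Nk[i] < _EMPTY:  # empty expert: posterior = prior
            m[i], beta[i], nu[i] = m0[i], hyper.beta0, hyper.nu0
            B[i] = hyper.B0
            continue
        Sxx = (X * r[:, i : i + 1]).T @ X
        B_inv = (B0_inv + Sxx
                 + hyper.beta0 * np.outer(m0[i], m0[i])
                 - beta[i] * np.outer(m[i], m[i]))
        B[i], _ = _spd_inverse(B_inv, f"gate precision scale B[{i}]^-1")
    return GatePosterior(m=m, beta=beta, B=B, nu=nu)


def vbm_experts(
    X: np.ndarray,
    Y: np.ndarray,
    r: np.ndarray,
    Upsilon: np.ndarray,
    hyper: Hyperparameters,
) -> ExpertPosterior:
    """Matrix-Normal-Wishart expert updates with the bias-augmented design.

    With Xt = [X 1] and V_i = diag(r_.i):
    L_i = (Xt'V_i Xt + Upsilon_i)^-1; What_i = L_i Xt'V_i Y;
    lam_i = lambda0 + N_i;
    Q_i^-1 = Q0^-1 + Y'V_i Y - What_i'(Xt'V_i Xt + Upsilon_i) What_i.
    """
    if np.any(Upsilon <= 0):
        raise ValueError("Upsilon must be strictly positive")
    N, d_x = X.shape
    d_y = Y.shape[1]
    M = r.shape[1]
    p = d_x + 1
    Xt = np.column_stack([X, np.ones(N)])
    Q0_inv, _ = _spd_inverse(hyper.Q0, "Q0")
    Nk = r.sum(axis=0)
    W_hat = np.zeros((M, p, d_y))
    L = np.empty((M, p, p))
    Q = np.empty((M, d_y, d_y))
    lam = hyper.lambda0 + Nk
    for i in range(M):
        if Nk[i] < _EMPTY:  # empty expert: posterior = prior
            L[i] = np.diag(1.0 / Upsilon[i])
            Q[i] = hyper.Q0
            lam[i] = hyper.lambda0
            continue
        w = r[:, i]
        G = (Xt * w[:, None]).T @ Xt + np.diag(Upsilon[i])  # Xt'V Xt + Ups
        L[i], _ = _spd_inverse(G, f"expert design Gram L[{i}]^-1")
        W_hat[i] = L[i] @ (Xt.T @ (w[:, None] * Y))
        Q_inv = Q0_inv + (Y * w[:, None]).T @ Y - W_hat[i].T @ G @ W_hat[i]
        Q[i], _ = _spd_inverse(Q_inv, f"expert noise scale Q[{i}]^-1")
    return ExpertPosterior(W_hat=W_hat, L=L, lam=lam, Q=Q)


def ard_statistic(experts: ExpertPosterior) -> np.ndarray:
    """xi_ij = d_y (L_i)_jj + lam_i * w_ij Q_i w_ij' for each expert row j."""
    d_y = experts.Q.shape[1]
    diagL = np.diagonal(experts.L, axis1=1, axis2=2)  # (M, p)
    quad = np.einsum("ipd,ide,ipe->ip", experts.W_hat, experts.Q, experts.W_hat)
    return d_y * diagL + experts.lam[:, None] * quad


def vbm_ard(experts: ExpertPosterior, hyper: Hyperparameters) -> ARDPosterior:
    """Gamma ARD updates: c_i = c0 + d_y/2, d_ij = d0 + xi_ij/2."""
    xi = ard_statistic(experts)
    if np.any(xi < 0):
        warnings.warn("negative ARD statistic clamped to zero", stacklevel=2)
        xi = np.maximum(xi, 0.0)
    d_y = experts.Q.shape[1]
    c = np.full(experts.n_experts, hyper.c0 + 0.5 * d_y)
    d = hyper.d0 + 0.5 * xi
    return ARDPosterior(c=c, d=d)


def _expected_log_dets(gates: GatePosterior, experts: ExpertPosterior) -> tuple[np.ndarray, np.ndarray]:
    """E[ln|Lambda_i|] and E[ln|chi_i|] under the Wishart posteriors."""
    d_x = gates.m.shape[1]
    d_y = experts.Q.shape[1]
    j_x = np.arange(1, d_x + 1)
    j_y = np.arange(1, d_y + 1)
    _, logdetB = np.linalg.slogdet(gates.B)
    _, logdetQ = np.linalg.slogdet(experts.Q)
    ln_lam = (digamma((gates.nu[:, None] + 1 - j_x) / 2).sum(axis=1)
              + d_x * np.log(2.0) + logdetB)
    ln_chi = (digamma((experts.lam[:, None] + 1 - j_y) / 2).sum(axis=1)
              + d_y * np.log(2.0) + logdetQ)
    return ln_lam, ln_chi


def _quad_terms(
    X: np.ndarray, Y: np.ndarray, gates: GatePosterior, experts: ExpertPosterior
) -> tuple[np.ndarray, np.ndarray]:
    """Expected Mahalanobis terms of the VBE step, both (N, M).

    varpi_ni = nu_i (x_n - m_i) B_i (x_n - m_i)' + d_x / beta_i
    xi_ni    = lam_i (y_n - xt_n What_i) Q_i (...)' + d_y xt_n L_i xt_n'
    """
    N, d_x = X.shape
    d_y = Y.shape[1]
    M = gates.n_experts
    Xt = np.column_stack([X, np.ones(N)])
    varpi = np.empty((N, M))
    xi = np.empty((N, M))
    for i in range(M):
        diff = X - gates.m[i]
        varpi[:, i] = (gates.nu[i] * np.einsum("nj,jk,nk->n", diff, gates.B[i], diff)
                       + d_x / gates.beta[i])
        resid = Y - Xt @ experts.W_hat[i]
        xi[:, i] = (experts.lam[i]
                    * np.einsum("nj,jk,nk->n", resid, experts.Q[i], resid)
                    + d_y * np.einsum("nj,jk,nk->n", Xt, experts.L[i], Xt))
    return varpi, xi


def vbe_step(
    X: np.ndarray,
    Y: np.ndarray,
    gates: GatePosterior,
    experts: ExpertPosterior,
    pi: np.ndarray,
) -> np.ndarray:
    """Responsibility update r_ni = gamma_ni / sum_l gamma_nl in log space.

    ln gamma_ni = ln pi_i + 0.5 (E[ln|Lambda_i|] + E[ln|chi_i|]
    - varpi_ni - xi_ni); rows are normalized by log-sum-exp so underflow
    never yields NaN.
    """
    ln_lam, ln_chi = _expected_log_dets(gates, experts)
    varpi, xi = _quad_terms(X, Y, gates, experts)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    log_gamma = log_pi[None, :] + 0.5 * (ln_lam + ln_chi - varpi - xi)
    log_r = log_gamma - logsumexp(log_gamma, axis=1, keepdims=True)
    return np.exp(log_r)


def update_mixing(r: np.ndarray) -> np.ndarray:
    """Point-estimate mixing weights pi_i = (1/N) sum_n r_ni."""
    return r.mean(axis=0)


def prune_experts(
    r: np.ndarray, pi: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop experts with pi_i < threshold; renormalize pi and the rows of r.

    Returns (keep_indices, r, pi). If all experts fall below the threshold
    the largest one is kept with a warning.
    """
    if threshold < 0:
        raise ValueError("prune threshold must be nonnegative")
    keep = np.flatnonzero(pi >= threshold)
    if keep.size == 0:
        warnings.warn("pruning would remove every expert; keeping the largest",
                      stacklevel=2)
        keep = np.array([int(np.argmax(pi))])
    if keep.size == len(pi):
        return keep, r, pi
    r = r[:, keep]
    r = r / r.sum(axis=1, keepdims=True)
    pi = pi[keep] / pi[keep].sum()
    return keep, r, pi


def _log_wishart_const(B: np.ndarray, nu: float) -> float:
    """ln of the W(Lambda|B, nu) normalizer (scale parameterization)."""
    d = len(B)
    _, logdet = np.linalg.slogdet(B)
    return -0.5 * nu * logdet - 0.5 * nu * d * np.log(2.0) - multigammaln(0.5 * nu, d)


def lower_bound(
    X: np.ndarray,
    Y: np.ndarray,
    r: np.ndarray,
    gates: GatePosterior,
    experts: ExpertPosterior,
    ard: ARDPosterior,
    pi: np.ndarray,
    hyper: Hyperparameters,
) -> float:
    """Evidence lower bound E_q[ln p(Y,X,Z,mu,Lambda,W,chi,a|pi)] - E_q[ln q].

    Assembled term by term from the conjugate-exponential family results:
    Gaussian-Wishart gate terms, matrix-Normal-Wishart expert terms, Gamma
    ARD terms, and the multinomial latent terms. Non-decreasing across VBEM
    passes; raises on a non-finite result naming the offending term.
    """
    N, d_x = X.shape
    d_y = Y.shape[1]
    p = d_x + 1
    M = gates.n_experts
    m0 = hyper.m0 if hyper.m0 is not None else np.zeros((M, d_x))
    ln_lam, ln_chi = _expected_log_dets(gates, experts)
    varpi, xi_nm = _quad_terms(X, Y, gates, experts)

    terms: dict[str, float] = {}

    # E[ln p(X|Z, mu, Lambda)] and E[ln p(Y|X, Z, W, chi)]
    terms["gate_data"] = float(
        0.5 * np.sum(r * (ln_lam[None, :] - d_x * np.log(2 * np.pi) - varpi)))
    terms["expert_data"] = float(
        0.5 * np.sum(r * (ln_chi[None, :] - d_y * np.log(2 * np.pi) - xi_nm)))

    # E[ln p(Z|pi)] - E[ln q(Z)]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), 0.0)
        log_r = np.where(r > 0, np.log(np.maximum(r, 1e-300)), 0.0)
    terms["latent"] = float(np.sum(r * (log_pi[None, :] - log_r)))

    # gate prior minus posterior entropy contributions
    B0_inv, _ = _spd_inverse(hyper.B0, "B0")
    lnC0_gate = _log_wishart_const(hyper.B0, hyper.nu0)
    g_prior = g_post = 0.0
    for i in range(M):
        dm = gates.m[i] - m0[i]
        g_prior += (0.5 * (d_x * np.log(hyper.beta0 / (2 * np.pi)) + ln_lam[i]
                           - d_x * hyper.beta0 / gates.beta[i]
                           - hyper.beta0 * gates.nu[i] * dm @ gates.B[i] @ dm)
                    + lnC0_gate + 0.5 * (hyper.nu0 - d_x - 1) * ln_lam[i]
                    - 0.5 * gates.nu[i] * np.trace(B0_inv @ gates.B[i]))
        g_post += (0.5 * (d_x * np.log(gates.beta[i] / (2 * np.pi)) + ln_lam[i] - d_x)
                   + _log_wishart_const(gates.B[i], gates.nu[i])
                   + 0.5 * (gates.nu[i] - d_x - 1) * ln_lam[i]
                   - 0.5 * gates.nu[i] * d_x)
    terms["gate_prior"] = float(g_prior)
    terms["gate_entropy"] = float(-g_post)

    # expert prior minus posterior entropy contributions
    Q0_inv, _ = _spd_inverse(hyper.Q0, "Q0")
    lnC0_exp = _log_wishart_const(hyper.Q0, hyper.lambda0)
    Ups = ard.Upsilon
    e_log_a = digamma(ard.c)[:, None] - np.log(ard.d)  # (M, p)
    xi_ard = ard_statistic(experts)
    e_prior = e_post = 0.0
    for i in range(M):
        _, logdetL = np.linalg.slogdet(experts.L[i])
        e_prior += (-0.5 * p * d_y * np.log(2 * np.pi)
                    + 0.5 * d_y * e_log_a[i].sum()
                    + 0.5 * p * ln_chi[i]
                    - 0.5 * np.sum(Ups[i] * xi_ard[i])
                    + lnC0_exp + 0.5 * (hyper.lambda0 - d_y - 1) * ln_chi[i]
                    - 0.5 * experts.lam[i] * np.trace(Q0_inv @ experts.Q[i]))
        e_post += (-0.5 * p * d_y * np.log(2 * np.pi)
                   - 0.5 * d_y * logdetL
                   + 0.5 * p * ln_chi[i]
                   - 0.5 * p * d_y
                   + _log_wishart_const(experts.Q[i], experts.lam[i])
                   + 0.5 * (experts.lam[i] - d_y - 1) * ln_chi[i]
                   - 0.5 * experts.lam[i] * d_y)
    terms["expert_prior"] = float(e_prior)
    terms["expert_entropy"] = float(-e_post)

    # ARD Gamma prior minus posterior entropy
    c0, d0 = hyper.c0, hyper.d0
    a_prior = np.sum(c0 * np.log(d0) - gammaln(c0)
                     + (c0 - 1) * e_log_a - d0 * Ups)
    a_post = np.sum(ard.c[:, None] * np.log(ard.d) - gammaln(ard.c)[:, None]
                    + (ard.c[:, None] - 1) * (digamma(ard.c)[:, None] - np.log(ard.d))
                    - ard.c[:, None])
    terms["ard_prior"] = float(a_prior)
    terms["ard_entropy"] = float(-a_post)

    total = sum(terms.values())
    if not np.isfinite(total):
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite lower bound; offending term(s): {bad}")
    return total


@dataclass
class VBState:
    """Full state of one VBEM run (one restart)."""

    r: np.ndarray
    pi: np.ndarray
    gates: GatePosterior
    experts: ExpertPosterior
    ard: ARDPosterior
    hyper: Hyperparameters
    lower_bound_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def lower_bound(self) -> float:
        return self.lower_bound_trace[-1]

    @property
    def n_experts(self) -> int:
        return len(self.pi)


def fit_single(
    X: np.ndarray,
    Y: np.ndarray,
    hyper: Hyperparameters,
    M_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune_threshold: float | None = None,
    seed: int | None = None,
) -> VBState:
    """One VBEM run: VBM (mixing -> gates -> experts -> ARD), VBE, prune.

    Stops when the relative lower-bound change drops below ``tol`` (only
    checked on passes where no expert was pruned) or after ``max_iter``
    passes. ``prune_threshold`` defaults to 1/(2N): experts supported by
    less than half a data point are removed.
    """
    N = len(X)
    if N <= X.shape[1] + 1:
        raise ValueError("need more samples than inputs + 1")
    if prune_threshold is None:
        prune_threshold = 1.0 / (2.0 * N)
    r, Upsilon, pi, hyper = init_state(X, Y, hyper, M_init, seed=seed)
    ard = None
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pi = update_mixing(r)
        keep, r, pi = prune_experts(r, pi, prune_threshold)
        pruned = keep.size < len(Upsilon)
        if pruned:
            Upsilon = Upsilon[keep]
            hyper = hyper.subset(keep)
        gates = vbm_gates(X, r, hyper)
        experts = vbm_experts(X, Y, r, Upsilon, hyper)
        ard = vbm_ard(experts, hyper)
        Upsilon = ard.Upsilon
        r = vbe_step(X, Y, gates, experts, pi)
        lb = lower_bound(X, Y, r, gates, experts, ard, pi, hyper)
        trace.append(lb)
        if len(trace) > 1 and not pruned:
            if abs(trace[-1] - trace[-2]) <= tol * abs(trace[-1]):
                converged = True
                break
    return VBState(r=r, pi=pi, gates=gates, experts=experts, ard=ard,
                   hyper=hyper, lower_bound_trace=trace, converged=converged)
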