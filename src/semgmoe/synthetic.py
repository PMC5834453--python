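"""Seeded generators of mixture-of-experts structured sEMG-like sessions.

The generative model mirrors the regression model the package fits: each
movement is a Gaussian cluster in feature space (the gate), and within a
cluster the force is a linear map of the (bias-augmented) feature vector
plus Gaussian noise (the expert).  Sessions are laid out as contiguous
movement blocks organised into repetitions, with rest blocks interleaved,
emulating a force-protocol recording session.  Rest is an explicit extra
"expert" with near-zero force output, labelled movement 0.

A separate generator produces a raw multichannel signal: zero-mean white
noise per channel, amplitude-modulated so that the per-window MAV/RMS
envelope tracks the active movement's cluster mean.  This is sufficient to
exercise windowing and feature extraction end to end; no physiological
sEMG model is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruthMoE",
    "SyntheticSession",
    "RawRecording",
    "make_ground_truth",
    "sample_session",
    "sample_raw_semg",
]


@dataclass
class GroundTruthMoE:
    """True parameters of a generating mixture of linear experts.

    Attributes
    ----------
    mu : (M, d_x) cluster means of the gating Gaussians.
    Lambda_inv : (M, d_x, d_x) SPD cluster covariances.
    W : (M, d_x + 1, d_y) expert weight matrices; last row is the bias.
    chi_inv : (M, d_y, d_y) SPD expert noise covariances.
    pi : (M,) mixing weights, nonnegative, summing to 1.
    """

    mu: np.ndarray
    Lambda_inv: np.ndarray
    W: np.ndarray
    chi_inv: np.ndarray
    pi: np.ndarray

    @property
    def n_experts(self) -> int:
        return self.mu.shape[0]

    @property
    def d_x(self) -> int:
        return self.mu.shape[1]

    @property
    def d_y(self) -> int:
        return self.W.shape[2]

    def __post_init__(self) -> None:
        for name in ("Lambda_inv", "chi_inv"):
            mats = getattr(self, name)
            for i, S in enumerate(mats):
                if not np.allclose(S, S.T):
                    raise ValueError(f"{name}[{i}] is not symmetric")
                np.linalg.cholesky(S)  # raises if not positive definite
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("pi must be nonnegative")

    def mean_force(self, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Noise-free force W_z'[x;1] for each row of X given expert labels."""
        Xt = np.column_stack([X, np.ones(len(X))])
        Y = np.empty((len(X), self.d_y))
        for i in range(self.n_experts):
            sel = labels == i + 1
            if sel.any():
                Y[sel] = Xt[sel] @ self.W[i]
        return Y


@dataclass
class SyntheticSession:
    """One generated session of paired features and forces.

    ``z`` holds true expert labels (1..M, 0 for rest), ``movement`` the
    movement id per sample (0 = rest), ``repetition`` the repetition id
    (1-based; rest rows carry the surrounding repetition's id).
    """

    X: np.ndarray
    Y: np.ndarray
    z: np.ndarray
    movement: np.ndarray
    repetition: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("session contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class RawRecording:
    """Raw multichannel amplitude-modulated signal with synchronized force."""

    emg: np.ndarray
    force: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    fs: float
    envelope: np.ndarray = field(repr=False)


def _random_spd(rng: np.random.Generator, d: int, spread: float) -> np.ndarray:
    """SPD matrix I + spread * A A' with A standard normal — eigenvalues >= 1."""
    A = rng.standard_normal((d, d)) * np.sqrt(spread / max(d, 1))
    return np.eye(d) + A @ A.T


def make_ground_truth(
    n_experts: int,
    d_x: int,
    d_y: int,
    separation: float = 8.0,
    noise_scale: float = 0.05,
    seed: int | None = None,
) -> GroundTruthMoE:
    """Draw a ground-truth mixture with well-separated gate clusters.

    Parameters
    ----------
    separation : minimum pairwise Euclidean distance enforced between the
        cluster means (the means are rescaled to meet it).
    noise_scale : standard-deviation scale of the expert observation noise.
        The default gives a within-movement noise floor of about 5% of the
        unit per-feature signal scale, matching the high signal-to-noise
        ratio of windowed sEMG features within a held movement; at this
        level expert-weight recovery at protocol-scale sample sizes is
        limited by sample size, not noise.
    """
    if n_experts < 1 or d_x < 1 or d_y < 1:
        raise ValueError("n_experts, d_x and d_y must all be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    # amplitude-like (nonnegative) cluster means: windowed sEMG features
    # are rectified amplitudes, so per-movement feature centroids live in
    # the positive orthant
    mu = np.abs(rng.standard_normal((n_experts, d_x)))
    if n_experts > 1:
        diff = mu[:, None, :] - mu[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        mind = dist[np.triu_indices(n_experts, 1)].min()
        if mind <= 1e-12:  # pathological draw; respace deterministically
            mu += separation * np.arange(n_experts)[:, None]
            diff = mu[:, None, :] - mu[None, :, :]
            mind = np.sqrt((diff**2).sum(-1))[np.triu_indices(n_experts, 1)].min()
        if mind < separation:
            mu *= separation / mind
    Lambda_inv = np.stack(
        [_random_spd(rng, d_x, 0.2) for _ in range(n_experts)]
    )
    W = rng.standard_normal((n_experts, d_x + 1, d_y))
    chi_inv = np.stack(
        [noise_scale**2 * _random_spd(rng, d_y, 0.2) for _ in range(n_experts)]
    )
    pi = rng.dirichlet(np.full(n_experts, 10.0))
    pi /= pi.sum()
    return GroundTruthMoE(mu=mu, Lambda_inv=Lambda_inv, W=W, chi_inv=chi_inv, pi=pi)


def _rest_expert(gt: GroundTruthMoE) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Parameters of the dedicated rest expert: origin cluster, ~zero force."""
    d_x, d_y = gt.d_x, gt.d_y
    mu = np.zeros(d_x)
    cov = 0.25 * np.eye(d_x)
    W = np.zeros((d_x + 1, d_y))
    noise = 1e-4 * np.eye(d_y)
    return mu, cov, W, noise


def sample_session(
    gt: GroundTruthMoE,
    n_per_block: int = 50,
    n_repetitions: int = 6,
    rest_fraction: float = 0.5,
    assignment: str = "cycle",
    seed: int | None = None,
) -> SyntheticSession:
    """Sample a block-structured session from the ground truth.

    Each repetition contains one block of ``n_per_block`` feature/force
    rows per movement, separated by rest blocks of
    ``round(rest_fraction * n_per_block)`` rows.  Movement block rows are
    drawn x ~ N(mu_i, Lambda_inv_i), y = W_i'[x;1] + e, e ~ N(0, chi_inv_i);
    rest rows come from the dedicated near-zero-force rest expert.

    ``assignment="cycle"`` (the protocol layout) visits every movement once
    per repetition; ``assignment="sample"`` draws each block's movement
    from the mixing weights ``gt.pi``, so empirical movement proportions
    converge to ``pi`` as the block count grows.
    """
    if n_per_block < 1:
        raise ValueError("n_per_block must be >= 1")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if not 0.0 <= rest_fraction:
        raise ValueError("rest_fraction must be nonnegative")
    if assignment not in ("cycle", "sample"):
        raise ValueError("assignment must be 'cycle' or 'sample'")
    rng = np.random.default_rng(seed)
    n_rest = int(round(rest_fraction * n_per_block))
    mu_r, cov_r, W_r, noise_r = _rest_expert(gt)

    X_parts, Y_parts, z_parts, mov_parts, rep_parts = [], [], [], [], []

    def draw_block(mu, cov, W, noise, n, label, rep):
        Xb = rng.multivariate_normal(mu, cov, size=n)
        Xt = np.column_stack([Xb, np.ones(n)])
        Yb = Xt @ W + rng.multivariate_normal(np.zeros(gt.d_y), noise, size=n)
        X_parts.append(Xb)
        Y_parts.append(Yb)
        z_parts.append(np.full(n, label))
        mov_parts.append(np.full(n, label))
        rep_parts.append(np.full(n, rep))

    for rep in range(1, n_repetitions + 1):
        if assignment == "cycle":
            order = np.arange(gt.n_experts)
        else:
            order = rng.choice(gt.n_experts, size=gt.n_experts, p=gt.pi)
        for i in order:
            if n_rest > 0:
                draw_block(mu_r, cov_r, W_r, noise_r, n_rest, 0, rep)
            draw_block(gt.mu[i], gt.Lambda_inv[i], gt.W[i], gt.chi_inv[i],
                       n_per_block, i + 1, rep)
        if n_rest > 0:
            draw_block(mu_r, cov_r, W_r, noise_r, n_rest, 0, rep)

    return SyntheticSession(
        X=np.vstack(X_parts),
        Y=np.vstack(Y_parts),
        z=np.concatenate(z_parts).astype(int),
        movement=np.concatenate(mov_parts).astype(int),
        repetition=np.concatenate(rep_parts).astype(int),
    )


def _slow_modulation(
    rng: np.random.Generator, n: int, cov: np.ndarray, knot_spacing: int
) -> np.ndarray:
    """Slowly varying zero-mean Gaussian drift: correlated knots, linear
    interpolation between them (timescale >> analysis-window length)."""
    d = cov.shape[0]
    n_knots = max(2, n // knot_spacing + 1)
    knots = rng.multivariate_normal(np.zeros(d), cov, size=n_knots)
    t_knots = np.linspace(0, n - 1, n_knots)
    t = np.arange(n)
    return np.column_stack(
        [np.interp(t, t_knots, knots[:, c]) for c in range(d)])


def sample_raw_semg(
    gt: GroundTruthMoE,
    fs: float = 2000.0,
    block_ms: float = 4000.0,
    n_repetitions: int = 6,
    rest_fraction: float = 0.75,
    baseline: float = 0.05,
    knot_ms: float = 500.0,
    sigma_rel: float = 0.25,
    seed: int | None = None,
) -> RawRecording:
    """Sample a raw amplitude-modulated multichannel signal.

    Each channel carries zero-mean Gaussian white noise whose standard
    deviation (the envelope) tracks the active movement: during a block of
    movement i the envelope is (mu_i + baseline) * exp(sigma_rel * u(t)),
    where u(t) is a slow unit-scale drift correlated across channels with
    the movement's cluster correlation, emulating multiplicative variation
    of activation strength within a held contraction; at rest it is the
    flat ``baseline``.  Per-window RMS therefore recovers the envelope
    (MAV recovers sqrt(2/pi) times it), and the synchronized force trace
    is the expert map evaluated at the instantaneous envelope,
    y(t) = W_i'[env(t); 1] + noise, so envelope and force co-vary within a
    movement just as features and forces do in the feature-space model.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if block_ms <= 0:
        raise ValueError("block_ms must be positive")
    rng = np.random.default_rng(seed)
    n_block = int(round(block_ms * fs / 1000.0))
    n_rest = int(round(rest_fraction * n_block))
    knot_spacing = max(1, int(round(knot_ms * fs / 1000.0)))
    d_x, d_y = gt.d_x, gt.d_y

    env_parts, force_parts, mov_parts, rep_parts = [], [], [], []

    def add_rest(n, rep):
        env_parts.append(np.full((n, d_x), baseline))
        force_parts.append(np.zeros((n, d_y)))
        mov_parts.append(np.zeros(n))
        rep_parts.append(np.full(n, rep))

    # unit-diagonal correlation of the within-movement drift
    corrs = []
    for i in range(gt.n_experts):
        s = np.sqrt(np.diag(gt.Lambda_inv[i]))
        corrs.append(gt.Lambda_inv[i] / np.outer(s, s))

    for rep in range(1, n_repetitions + 1):
        for i in range(gt.n_experts):
            if n_rest > 0:
                add_rest(n_rest, rep)
            u = _slow_modulation(rng, n_block, corrs[i], knot_spacing)
            env = (gt.mu[i] + baseline) * np.exp(sigma_rel * u)
            env_aug = np.column_stack([env, np.ones(n_block)])
            noise = rng.multivariate_normal(np.zeros(d_y), gt.chi_inv[i],
                                            size=n_block)
            env_parts.append(env)
            force_parts.append(env_aug @ gt.W[i] + noise)
            mov_parts.append(np.full(n_block, i + 1))
            rep_parts.append(np.full(n_block, rep))
        if n_rest > 0:
            add_rest(n_rest, rep)

    envelope = np.vstack(env_parts)
    force = np.vstack(force_parts)
    movement = np.concatenate(mov_parts).astype(int)
    repetition = np.concatenate(rep_parts).astype(int)
    emg = envelope * rng.standard_normal(envelope.shape)
    return RawRecording(emg=emg, force=force, stimulus=movement,
                        repetition=repetition, fs=fs, envelope=envelope)
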