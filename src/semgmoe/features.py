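"""Windowed time-domain sEMG feature extraction and dataset preparation.

Implements the standard preprocessing chain for sEMG force regression:
overlapping sliding windows (default 400 ms / 800 samples with a 10 ms /
20 sample increment at 2 kHz), low-dimensional time-domain features per
channel (MAV, WL, RMS), a rectified low-pass "FILT" feature, repetition-
based train/test splitting, regular-interval row subsampling, and
train-statistics standardization.

Windows are labelled by their last sample (causal convention): a window's
feature vector only uses signal up to the instant it is labelled with.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WindowConfig",
    "FeatureDataset",
    "Standardizer",
    "sliding_windows",
    "n_windows",
    "window_last_indices",
    "mav",
    "wl",
    "rms",
    "filt_features",
    "extract_features",
    "split_by_repetition",
    "subsample_rows",
    "standardize",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: sampling rate, length and increment in samples."""

    fs: float = 2000.0
    window_len: int = 800
    increment: int = 20

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 1 <= self.increment <= self.window_len:
            raise ValueError("increment must satisfy 1 <= increment <= window_len")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @classmethod
    def from_ms(cls, fs: float, window_ms: float, increment_ms: float) -> "WindowConfig":
        return cls(fs=fs,
                   window_len=int(round(window_ms * fs / 1000.0)),
                   increment=int(round(increment_ms * fs / 1000.0)))


def n_windows(T: int, window_len: int, increment: int) -> int:
    """Number of full windows in a length-T series: floor((T-len)/inc) + 1."""
    if T < window_len:
        raise ValueError(f"series length {T} shorter than window length {window_len}")
    return (T - window_len) // increment + 1


def sliding_windows(signal: np.ndarray, cfg: WindowConfig) -> np.ndarray:
    """Overlapping windows of a (T,) or (T, channels) series.

    Returns an array of shape (n_windows, window_len) or
    (n_windows, channels, window_len) — the window samples always run
    along the last axis, as the feature functions expect; window k covers
    samples [k*increment, k*increment + window_len).
    """
    signal = np.asarray(signal)
    T = signal.shape[0]
    k = n_windows(T, cfg.window_len, cfg.increment)
    win = sliding_window_view(signal, cfg.window_len, axis=0)
    return win[:: cfg.increment][:k]


def window_last_indices(T: int, cfg: WindowConfig) -> np.ndarray:
    """Index of the last sample of each window (used to label windows)."""
    k = n_windows(T, cfg.window_len, cfg.increment)
    return np.arange(k) * cfg.increment + cfg.window_len - 1


def _check_window(window: np.ndarray, min_len: int = 1) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < min_len:
        raise ValueError(f"window must have at least {min_len} samples")
    return window


def mav(window: np.ndarray) -> np.ndarray:
    """Mean absolute value (1/N_w) * sum |x_n| along the last axis."""
    return np.mean(np.abs(_check_window(window)), axis=-1)


def wl(window: np.ndarray) -> np.ndarray:
    """Waveform length: total variation sum |x_n - x_{n-1}| along the last axis."""
    w = _check_window(window, min_len=2)
    return np.sum(np.abs(np.diff(w, axis=-1)), axis=-1)


def rms(window: np.ndarray) -> np.ndarray:
    """Root mean square sqrt((1/N_w) * sum x_n^2) along the last axis."""
    return np.sqrt(np.mean(_check_window(window) ** 2, axis=-1))


_WINDOWED_FES = {"mav": mav, "wl": wl, "rms": rms}


def filt_features(
    signal: np.ndarray,
    fs: float,
    cutoff: float = 2.0,
    order: int = 2,
    subsample: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Rectify, zero-phase low-pass filter and subsample a per-channel series.

    Applies |.|, a forward-backward Butterworth filter of the given order
    and cutoff (zero phase, unit DC gain), and keeps every ``subsample``-th
    sample starting at index 0.  Returns (features, kept_indices) so labels
    can be subsampled in lockstep.  Training and test series should be
    passed separately (the filter is run per series).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float).T).T  # (T, C)
    if fs <= 2 * cutoff:
        raise ValueError("fs must exceed twice the cutoff frequency")
    warmup = 3 * order + 1
    if signal.shape[0] <= warmup:
        raise ValueError(
            f"series of length {signal.shape[0]} shorter than filter warm-up {warmup}"
        )
    b, a = butter(order, cutoff, btype="low", fs=fs)
    env = filtfilt(b, a, np.abs(signal), axis=0)
    idx = np.arange(0, env.shape[0], subsample)
    return env[idx], idx


@dataclass
class FeatureDataset:
    """Paired feature/force matrices with per-row movement and repetition ids."""

    X: np.ndarray
    Y: np.ndarray
    movement: np.ndarray
    repetition: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.Y) == len(self.movement) == len(self.repetition) == n):
            raise ValueError("all arrays must share the leading dimension")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def take(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(self.X[idx], self.Y[idx],
                              self.movement[idx], self.repetition[idx])


class Standardizer(BaseEstimator, TransformerMixin):
    """Zero-mean/unit-variance scaling with statistics from the training set.

    Like a standard scaler but raises a named-column error on constant
    training columns (a zero-SD feature carries no information and would
    blow up to +-inf) and exposes an exact inverse transform.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        bad = np.flatnonzero(self.scale_ == 0)
        if bad.size:
            raise ValueError(f"training column(s) {bad.tolist()} have zero variance")
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def standardize(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Standardizer]:
    """Standardize train and (optionally) test with training statistics only."""
    sc = Standardizer().fit(train)
    return sc.transform(train), None if test is None else sc.transform(test), sc


def split_by_repetition(
    ds: FeatureDataset, test_reps: set[int] | None = None
) -> tuple[FeatureDataset, FeatureDataset]:
    """Split rows by repetition id; default held-out repetitions are {2, 5}."""
    import warnings

    if test_reps is None:
        test_reps = {2, 5}
    mask = np.isin(ds.repetition, list(test_reps))
    if mask.all() or (~mask).all():
        warnings.warn("repetition split produced an empty side", stacklevel=2)
    return ds.take(~mask), ds.take(mask)


def subsample_rows(ds: FeatureDataset, factor: int) -> FeatureDataset:
    """Keep every ``factor``-th row (regular-interval subsampling from row 0)."""
    if factor < 1:
        raise ValueError("subsampling factor must be >= 1")
    return ds.take(np.arange(0, ds.n_samples, factor))


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs where mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    stops = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def extract_features(
    emg: np.ndarray,
    force: np.ndarray,
    stimulus: np.ndarray,
    repetition: np.ndarray,
    fe: str = "rms",
    cfg: WindowConfig | None = None,
    cutoff: float = 2.0,
    order: int = 2,
    filt_subsample: int = 200,
    row_mask: np.ndarray | None = None,
) -> FeatureDataset:
    """Extract a FeatureDataset from a raw recording.

    For the windowed features (mav/wl/rms) the signal is segmented into
    overlapping windows; each window's row carries the force, movement and
    repetition of its last sample.  For ``fe="filt"`` the rectified
    low-passed envelope is subsampled at regular intervals and rows carry
    the labels at the kept sample indices.

    ``row_mask`` restricts extraction to contiguous runs of selected raw
    samples (used to window training and test repetitions separately so no
    window straddles the split); windows never cross run boundaries.
    """
    emg = np.asarray(emg, dtype=float)
    force = np.asarray(force, dtype=float)
    stimulus = np.asarray(stimulus)
    repetition = np.asarray(repetition)
    if cfg is None:
        cfg = WindowConfig()
    if row_mask is None:
        row_mask = np.ones(emg.shape[0], dtype=bool)
    runs = _contiguous_runs(np.asarray(row_mask, dtype=bool))

    X_parts, Y_parts, mov_parts, rep_parts = [], [], [], []
    for start, stop in runs:
        seg = slice(start, stop)
        if fe == "filt":
            feats, kept = filt_features(emg[seg], cfg.fs, cutoff=cutoff,
                                        order=order, subsample=filt_subsample)
            lab = kept + start
        elif fe in _WINDOWED_FES:
            if stop - start < cfg.window_len:
                continue
            win = sliding_windows(emg[seg], cfg)  # (k, C, len)
            feats = _WINDOWED_FES[fe](win)
            lab = window_last_indices(stop - start, cfg) + start
        else:
            raise ValueError(f"unknown feature extraction '{fe}'")
        X_parts.append(feats)
        Y_parts.append(force[lab])
        mov_parts.append(stimulus[lab])
        rep_parts.append(repetition[lab])

    if not X_parts:
        raise ValueError("no segment long enough to extract a single window")
    return FeatureDataset(
        X=np.vstack(X_parts),
        Y=np.vstack(Y_parts),
        movement=np.concatenate(mov_parts).astype(int),
        repetition=np.concatenate(rep_parts).astype(int),
    )


def prepare_datasets(
    emg: np.ndarray,
    force: np.ndarray,
    stimulus: np.ndarray,
    repetition: np.ndarray,
    fe: str = "rms",
    cfg: WindowConfig | None = None,
    test_reps: set[int] | None = None,
    train_subsample: int = 10,
    filt_subsample: int = 200,
) -> tuple[FeatureDataset, FeatureDataset, Standardizer, Standardizer]:
    """Full preprocessing protocol from a raw recording to model-ready data.

    Steps: split raw rows into training and held-out repetitions (default
    test repetitions {2, 5}); standardize the raw signals with training
    statistics; extract features separately per side so no window straddles
    the split; subsample the training rows; standardize the features with
    training statistics.  Returns (train, test, raw_standardizer,
    feature_standardizer).
    """
    if test_reps is None:
        test_reps = {2, 5}
    repetition = np.asarray(repetition)
    test_mask = np.isin(repetition, list(test_reps))

    raw_sc = Standardizer().fit(np.column_stack([emg, force])[~test_mask])
    both = raw_sc.transform(np.column_stack([emg, force]))
    d_c = emg.shape[1]
    emg_s, force_s = both[:, :d_c], both[:, d_c:]

    kw = dict(fe=fe, cfg=cfg, filt_subsample=filt_subsample)
    train = extract_features(emg_s, force_s, stimulus, repetition,
                             row_mask=~test_mask, **kw)
    test = extract_features(emg_s, force_s, stimulus, repetition,
                            row_mask=test_mask, **kw)
    train = subsample_rows(train, train_subsample)

    feat_sc = Standardizer().fit(train.X)
    train = replace(train, X=feat_sc.transform(train.X))
    test = replace(test, X=feat_sc.transform(test.X))
    return train, test, raw_sc, feat_sc
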