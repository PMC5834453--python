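"""Session and model serialization.

Sessions travel as delimited text (one row per raw sample: channels,
forces, movement/stimulus, repetition, with the sampling rate in a header
comment) or as MATLAB files in the NinaPro dialect (fields ``emg``,
``force``, ``stimulus``/``restimulus``, ``repetition``/``rerepetition``).
Fitted models round-trip through JSON with every posterior parameter, the
mixing weights, the lower-bound trace and the standardizer statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from ._vb import ARDPosterior, ExpertPosterior, GatePosterior, Hyperparameters
from .features import Standardizer
from .moe import BayesianMixtureOfExperts

MODEL_SCHEMA_VERSION = 1

__all__ = ["SessionFile", "RunConfig", "read_session", "write_session",
           "save_model", "load_model"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable losslessly as JSON.

    A (input files, RunConfig, seed) triple fully determines a pipeline
    run.
    """

    fe: str = "rms"
    fs: float = 2000.0
    window_ms: float = 400.0
    increment_ms: float = 10.0
    filt_cutoff_hz: float = 2.0
    filt_order: int = 2
    filt_subsample: int = 200
    test_reps: tuple[int, ...] = (2, 5)
    train_subsample: int = 10
    n_experts: int = 10
    n_restarts: int = 100
    max_iter: int = 200
    tol: float = 1e-6
    prune_threshold: float | None = None
    beta0: float = 0.01
    c0: float = 0.01
    d0: float = 0.0001
    sa_n_lhs: int = 2000
    sa_groups: tuple[tuple[int, ...], ...] | None = None
    seed: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config field(s): {sorted(extra)}")
        raw["test_reps"] = tuple(raw.get("test_reps", (2, 5)))
        if raw.get("sa_groups") is not None:
            raw["sa_groups"] = tuple(tuple(g) for g in raw["sa_groups"])
        return cls(**raw)


@dataclass
class SessionFile:
    """Raw recording: per-sample signals, forces, movement and repetition ids."""

    emg: np.ndarray
    force: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    fs: float = 2000.0

    def __post_init__(self) -> None:
        T = len(self.emg)
        for name in ("force", "stimulus", "repetition"):
            if len(getattr(self, name)) != T:
                raise ValueError(
                    f"array '{name}' has length {len(getattr(self, name))}, "
                    f"expected {T} (same as emg)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def write_session(path: str | Path, session: SessionFile, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        cols = {f"emg_{c+1}": session.emg[:, c] for c in range(session.emg.shape[1])}
        cols.update({f"force_{k+1}": session.force[:, k]
                     for k in range(session.force.shape[1])})
        cols["stimulus"] = session.stimulus
        cols["repetition"] = session.repetition
        with open(path, "w") as fh:
            fh.write(f"# fs={session.fs}\n")
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)
    elif dialect == "ninapro_mat":
        savemat(path, {
            "emg": session.emg, "force": session.force,
            "stimulus": session.stimulus.reshape(-1, 1),
            "repetition": session.repetition.reshape(-1, 1),
            "frequency": np.array([[session.fs]]),
        })
    else:
        raise ValueError(f"unknown dialect '{dialect}'")


def read_session(path: str | Path, dialect: str = "tsv") -> SessionFile:
    """Load a session from delimited text or a NinaPro-dialect .mat file."""
    path = Path(path)
    if dialect == "tsv":
        fs = 2000.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# fs="):
                fs = float(first.strip().split("=", 1)[1])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        emg_cols = [c for c in df.columns if c.startswith("emg_")]
        force_cols = [c for c in df.columns if c.startswith("force_")]
        for need in (emg_cols, force_cols):
            if not need:
                raise ValueError(f"{path}: no emg_*/force_* columns found")
        for need in ("stimulus", "repetition"):
            if need not in df.columns:
                raise ValueError(f"{path}: missing column '{need}'")
        return SessionFile(
            emg=df[emg_cols].to_numpy(float),
            force=df[force_cols].to_numpy(float),
            stimulus=df["stimulus"].to_numpy(int),
            repetition=df["repetition"].to_numpy(int),
            fs=fs,
        )
    if dialect == "ninapro_mat":
        raw = loadmat(path)
        def pick(*names):
            for n in names:
                if n in raw:
                    return raw[n]
            raise ValueError(f"{path}: missing field {names[0]!r}")
        emg = np.asarray(pick("emg"), dtype=float)
        force = np.asarray(pick("force"), dtype=float)
        stim = np.asarray(pick("restimulus", "stimulus")).ravel().astype(int)
        rep = np.asarray(pick("rerepetition", "repetition")).ravel().astype(int)
        fs = float(np.asarray(raw.get("frequency", 2000.0)).ravel()[0])
        return SessionFile(emg=emg, force=force, stimulus=stim,
                           repetition=rep, fs=fs)
    raise ValueError(f"unknown dialect '{dialect}'")


def _arr(x) -> list:
    return np.asarray(x).tolist()


def save_model(path: str | Path, model: BayesianMixtureOfExperts,
               standardizer: Standardizer | None = None) -> None:
    """Serialize a fitted model (all posteriors, weights, bound trace) to JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "params": model.get_params(),
        "gates": {"m": _arr(model.gates_.m), "beta": _arr(model.gates_.beta),
                  "B": _arr(model.gates_.B), "nu": _arr(model.gates_.nu)},
        "experts": {"W_hat": _arr(model.experts_.W_hat), "L": _arr(model.experts_.L),
                    "lam": _arr(model.experts_.lam), "Q": _arr(model.experts_.Q)},
        "ard": {"c": _arr(model.ard_.c), "d": _arr(model.ard_.d)},
        "weights": _arr(model.weights_),
        "lower_bound_trace": _arr(model.lower_bound_trace_),
        "converged": bool(model.converged_),
        "n_features_in": int(model.n_features_in_),
        "n_outputs": int(model.n_outputs_),
        "hyper": {"d_x": model.hyper_.d_x, "d_y": model.hyper_.d_y,
                  "beta0": model.hyper_.beta0, "nu0": model.hyper_.nu0,
                  "lambda0": model.hyper_.lambda0, "c0": model.hyper_.c0,
                  "d0": model.hyper_.d0, "B0": _arr(model.hyper_.B0),
                  "Q0": _arr(model.hyper_.Q0),
                  "m0": None if model.hyper_.m0 is None else _arr(model.hyper_.m0)},
    }
    if standardizer is not None:
        payload["standardizer"] = {"mean": _arr(standardizer.mean_),
                                   "scale": _arr(standardizer.scale_)}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[BayesianMixtureOfExperts, Standardizer | None]:
    """Reconstruct a fitted model (and optional standardizer) from JSON."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})")
    model = BayesianMixtureOfExperts(**payload["params"])
    A = lambda x: np.asarray(x, dtype=float)
    model.gates_ = GatePosterior(m=A(payload["gates"]["m"]),
                                 beta=A(payload["gates"]["beta"]),
                                 B=A(payload["gates"]["B"]),
                                 nu=A(payload["gates"]["nu"]))
    model.experts_ = ExpertPosterior(W_hat=A(payload["experts"]["W_hat"]),
                                     L=A(payload["experts"]["L"]),
                                     lam=A(payload["experts"]["lam"]),
                                     Q=A(payload["experts"]["Q"]))
    model.ard_ = ARDPosterior(c=A(payload["ard"]["c"]), d=A(payload["ard"]["d"]))
    model.weights_ = A(payload["weights"])
    model.lower_bound_trace_ = A(payload["lower_bound_trace"])
    model.lower_bound_ = float(model.lower_bound_trace_[-1])
    model.converged_ = payload["converged"]
    model.n_experts_ = len(model.weights_)
    model.n_features_in_ = payload["n_features_in"]
    model.n_outputs_ = payload["n_outputs"]
    h = payload["hyper"]
    model.hyper_ = Hyperparameters(
        d_x=h["d_x"], d_y=h["d_y"], beta0=h["beta0"], nu0=h["nu0"],
        lambda0=h["lambda0"], c0=h["c0"], d0=h["d0"],
        B0=A(h["B0"]), Q0=A(h["Q0"]),
        m0=None if h["m0"] is None else A(h["m0"]))
    sc = None
    if "standardizer" in payload:
        sc = Standardizer()
        sc.mean_ = A(payload["standardizer"]["mean"])
        sc.scale_ = A(payload["standardizer"]["scale"])
    return model, sc
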