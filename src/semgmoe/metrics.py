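"""Regression and classification metrics for force-protocol sessions.

NRMSE normalizes the RMS error by the range of the reference force; R^2 is
the usual coefficient of determination and may go negative on restricted
segments whose errors do not sum to zero. Gate-based classification is
unsupervised, so experts are mapped to movement labels by majority vote on
the training rows they win; accuracies and row-normalized confusion
matrices (rows = true class) are reported per pattern and overall. The
center-segment mask keeps only the middle third of each movement block,
removing the ambiguous rest-to-movement transition samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationReport",
    "nrmse",
    "r2",
    "map_experts_to_movements",
    "classification_accuracy",
    "confusion_matrix",
    "center_segment_labels",
    "evaluate_predictions",
]


def _columns(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    if y.ndim == 1:
        return y[:, None], y_hat[:, None], True
    return y, y_hat, False


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray | float:
    """Root-mean-square error divided by the range of the reference y, per DoF."""
    y, y_hat, scalar = _columns(y, y_hat)
    rng = y.max(axis=0) - y.min(axis=0)
    if np.any(rng == 0):
        bad = np.flatnonzero(rng == 0).tolist()
        raise ValueError(f"reference signal has zero range in DoF(s) {bad}")
    out = np.sqrt(np.mean((y - y_hat) ** 2, axis=0)) / rng
    return float(out[0]) if scalar else out


def r2(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray | float:
    """Coefficient of determination 1 - SS_res/SS_tot per DoF (may be negative)."""
    y, y_hat, scalar = _columns(y, y_hat)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        bad = np.flatnonzero(ss_tot == 0).tolist()
        raise ValueError(f"reference signal has zero variance in DoF(s) {bad}")
    out = 1.0 - np.sum((y - y_hat) ** 2, axis=0) / ss_tot
    return float(out[0]) if scalar else out


def map_experts_to_movements(
    winners: np.ndarray, movements: np.ndarray, n_experts: int | None = None
) -> dict[int, int]:
    """Majority-vote mapping from expert index to movement label.

    Each expert maps to the most frequent movement among the rows it wins;
    ties break to the lower movement id; experts that win no row map to
    rest (0).
    """
    winners = np.asarray(winners)
    movements = np.asarray(movements)
    if winners.shape != movements.shape:
        raise ValueError("winners and movements must have the same length")
    if n_experts is None:
        n_experts = int(winners.max()) + 1 if winners.size else 0
    mapping = {}
    for i in range(n_experts):
        labs = movements[winners == i]
        if labs.size == 0:
            mapping[i] = 0
            continue
        vals, counts = np.unique(labs, return_counts=True)  # vals sorted asc
        mapping[i] = int(vals[np.argmax(counts)])  # argmax ties -> lowest id
    return mapping


def classification_accuracy(
    pred: np.ndarray, true: np.ndarray, per_pattern: bool = False
):
    """Proportion of correctly classified instances, overall or per pattern."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same length")
    if pred.size == 0:
        raise ValueError("empty input")
    if not per_pattern:
        return float(np.mean(pred == true))
    return {int(m): float(np.mean(pred[true == m] == m))
            for m in np.unique(true)}


def confusion_matrix(
    pred: np.ndarray, true: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized confusion matrix (rows = true class) and its labels."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if labels is None:
        labels = np.unique(np.concatenate([true, pred]))
    idx = {int(v): k for k, v in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)))
    for t, p in zip(true, pred):
        C[idx[int(t)], idx[int(p)]] += 1
    row = C.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        C = np.where(row > 0, C / np.maximum(row, 1), 0.0)
    return C, np.asarray(labels)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, stop, label) runs, half-open."""
    labels = np.asarray(labels)
    out = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            out.append((start, k, int(labels[start])))
            start = k
    return out


@dataclass
class EvaluationReport:
    """Combined regression and classification summary of one test split."""

    nrmse_per_dof: np.ndarray
    r2_per_dof: np.ndarray
    nrmse_mean: float
    r2_mean: float
    accuracy: float
    accuracy_per_pattern: dict[int, float]
    accuracy_center_segment: float
    confusion: np.ndarray        # row-normalized, rows = true class
    confusion_labels: np.ndarray

    def to_dict(self) -> dict:
        return {
            "nrmse_per_dof": self.nrmse_per_dof.tolist(),
            "r2_per_dof": self.r2_per_dof.tolist(),
            "nrmse_mean": self.nrmse_mean,
            "r2_mean": self.r2_mean,
            "accuracy": self.accuracy,
            "accuracy_per_pattern": {str(k): v for k, v in
                                     self.accuracy_per_pattern.items()},
            "accuracy_center_segment": self.accuracy_center_segment,
            "confusion_matrix": self.confusion.tolist(),
            "confusion_labels": self.confusion_labels.tolist(),
        }


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    movements_true: np.ndarray,
    movements_pred: np.ndarray,
) -> EvaluationReport:
    """Assemble the full report for one held-out split.

    Regression metrics per force DoF plus gate-classification accuracies
    (continuous, per pattern, and on center segments only) and the
    row-normalized confusion matrix.
    """
    nr = np.atleast_1d(nrmse(y_true, y_pred))
    rr = np.atleast_1d(r2(y_true, y_pred))
    mask = center_segment_labels(movements_true)
    C, labels = confusion_matrix(movements_pred, movements_true)
    return EvaluationReport(
        nrmse_per_dof=nr,
        r2_per_dof=rr,
        nrmse_mean=float(nr.mean()),
        r2_mean=float(rr.mean()),
        accuracy=classification_accuracy(movements_pred, movements_true),
        accuracy_per_pattern=classification_accuracy(
            movements_pred, movements_true, per_pattern=True),
        accuracy_center_segment=classification_accuracy(
            movements_pred[mask], movements_true[mask]),
        confusion=C,
        confusion_labels=labels,
    )


def center_segment_labels(movements: np.ndarray) -> np.ndarray:
    """Mask keeping the middle third of each non-rest movement block.

    Each contiguous non-rest block of length n is split into three
    segments of sizes (n//3, n//3 + n%3, n//3) — the middle segment
    absorbs the remainder — and only its middle segment is kept. Rest
    blocks are fully retained.
    """
    movements = np.asarray(movements)
    mask = np.zeros(len(movements), dtype=bool)
    for start, stop, lab in _runs(movements):
        if lab == 0:
            mask[start:stop] = True
            continue
        n = stop - start
        third = n // 3
        mask[start + third : stop - third] = True
    return mask
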