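"""Rejection thresholding and F-beta threshold selection.

A softmax classifier forced to output a species for every read will
mislabel reads from taxa with shared or missing barcodes.  A binarization
threshold ``t`` rejects any read whose top-class probability falls below
``t``, trading recall (rejected reads) for precision.  The trade-off is
scored with the F-beta measure at a small beta (default 0.3), which
weights precision heavily — false species detections are worse than
discarded reads.  A threshold of 0.9 is the working default.

Precision and recall are micro-averaged over reads, with recall
denominated by *all* reads, so rejection costs recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REJECTED",
    "ThresholdConfig",
    "classify_with_threshold",
    "accuracy_with_rejection",
    "fbeta",
    "select_threshold",
]

#: Label value marking a rejected (below-threshold) prediction.
REJECTED = -1


def _default_grid() -> list[float]:
    return [round(0.05 * i, 2) for i in range(21)]


@dataclass
class ThresholdConfig:
    """Threshold selection parameters.

    ``binarization_threshold`` is the working acceptance threshold;
    ``beta`` weights precision against recall in the F-beta score;
    ``threshold_grid`` lists the candidate thresholds to scan.
    """

    binarization_threshold: float = 0.9
    beta: float = 0.3
    threshold_grid: list[float] = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        if not 0.0 <= self.binarization_threshold <= 1.0:
            raise ValueError("binarization_threshold must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if any(not 0.0 <= t <= 1.0 for t in self.threshold_grid):
            raise ValueError("threshold grid values must be in [0, 1]")


def classify_with_threshold(probs: np.ndarray, t: float) -> np.ndarray:
    """Argmax labels with rejection: row -> argmax class if the maximum
    probability is >= ``t``, else :data:`REJECTED`.

    Exact argmax ties resolve to the lowest class index.  Rows containing
    NaN (unclassifiable reads) are rejected.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be a 2-D (reads x classes) matrix")
    labels = np.argmax(probs, axis=1)
    top = probs[np.arange(len(probs)), labels]
    accept = top >= t  # NaN compares False -> rejected
    return np.where(accept, labels, REJECTED)


def accuracy_with_rejection(
    pred_labels: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """``(accuracy over accepted reads, discard rate)``.

    The accuracy is ``NaN`` when every read was rejected (undefined).
    ``truth`` must contain no rejected markers.
    """
    pred_labels = np.asarray(pred_labels)
    truth = np.asarray(truth)
    if pred_labels.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {pred_labels.shape} predictions vs "
            f"{truth.shape} truth labels"
        )
    if np.any(truth == REJECTED):
        raise ValueError("truth labels may not contain the rejected marker")
    accepted = pred_labels != REJECTED
    n = len(truth)
    discard_rate = float((~accepted).sum() / n) if n else 0.0
    if not accepted.any():
        return float("nan"), discard_rate
    acc = float(np.mean(pred_labels[accepted] == truth[accepted]))
    return acc, discard_rate


def fbeta(precision: float, recall: float, beta: float) -> float:
    """F-beta: ``(1 + beta^2) P R / (beta^2 P + R)``; 0 when P = R = 0.

    ``beta < 1`` favours precision; ``beta = 1`` is the harmonic mean.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    denom = beta * beta * precision + recall
    if denom == 0 or not np.isfinite(denom):
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def select_threshold(
    probs: np.ndarray,
    truth: np.ndarray,
    config: ThresholdConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Scan the threshold grid and pick the F-beta-maximising threshold.

    At each grid point ``t``: precision = correct accepted / accepted,
    recall = correct accepted / total reads.  Ties in F-beta resolve
    toward the *larger* (stricter) threshold, since false positives are
    the stated priority.  Returns ``(best_t, report)`` with one report row
    per grid point (columns ``t, precision, recall, f_beta,
    discard_rate``).
    """
    config = config or ThresholdConfig()
    if not config.threshold_grid:
        raise ValueError("empty threshold grid")
    truth = np.asarray(truth)
    n = len(truth)
    if n == 0:
        raise ValueError("empty evaluation set")
    rows = []
    for t in config.threshold_grid:
        labels = classify_with_threshold(probs, t)
        accepted = labels != REJECTED
        n_acc = int(accepted.sum())
        correct = int(np.sum(labels[accepted] == truth[accepted]))
        precision = correct / n_acc if n_acc else float("nan")
        recall = correct / n
        score = fbeta(precision, recall, config.beta) if n_acc else 0.0
        rows.append(
            {
                "t": t,
                "precision": precision,
                "recall": recall,
                "f_beta": score,
                "discard_rate": 1.0 - n_acc / n,
            }
        )
    report = pd.DataFrame(rows)
    best = report.sort_values(["f_beta", "t"], ascending=[False, False]).iloc[0]
    return float(best["t"]), report
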