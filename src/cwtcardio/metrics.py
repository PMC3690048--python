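"""Confusion-matrix construction and detector statistics.

The table convention throughout is: row T column P = TP, row T column N =
FN, row F column P = FP, row F column N = TN.  Beat-detection tables count
true negatives at sample level (every ECG sample that is correctly not a
beat), which is why TN dwarfs the other cells.

One naming trap is handled explicitly: the published evaluation tables this
package regression-tests against label overall accuracy ``(TP+TN)/total``
as "Precision".  :func:`accuracy` implements that quantity; the statistic
usually called precision (positive predictive value, ``TP/(TP+FP)``) is
available separately as :func:`ppv`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "UndefinedStatisticError",
    "match_events",
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "correct_rate",
    "pool",
    "mean_stat",
    "roc_points",
    "round_half_up",
    "load_reference_tables",
    "cm_from_dict",
    "DEFAULT_MATCH_TOLERANCE_S",
]

DEFAULT_MATCH_TOLERANCE_S = 0.05


class UndefinedStatisticError(ZeroDivisionError):
    """A statistic's denominator is zero; the message names the statistic."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts (all nonnegative integers)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def match_events(truth, detected, tolerance_s: float,
                 n_samples: int) -> ConfusionMatrix:
    """Score detected event times against ground truth.

    Greedy one-to-one matching over the two sorted time lists: a truth/
    detection pair within ``tolerance_s`` is a TP, unmatched truth events
    are FN, unmatched detections are FP, and TN fills up to ``n_samples``
    (sample-level negative counting).  For sorted lists with a uniform
    window this sequential greedy matching attains the maximum possible
    number of pairs.
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance must be positive")
    truth = np.asarray(truth, dtype=float)
    detected = np.asarray(detected, dtype=float)
    if np.any(np.diff(truth) < 0) or np.any(np.diff(detected) < 0):
        raise ValueError("event lists must be sorted")
    tp = 0
    i = j = 0
    while i < len(truth) and j < len(detected):
        if abs(truth[i] - detected[j]) <= tolerance_s:
            tp += 1
            i += 1
            j += 1
        elif detected[j] < truth[i] - tolerance_s:
            j += 1
        else:
            i += 1
    fn = len(truth) - tp
    fp = len(detected) - tp
    if n_samples < tp + fn + fp:
        raise ValueError(
            f"n_samples={n_samples} smaller than the event count {tp + fn + fp}"
        )
    return ConfusionMatrix(TP=tp, FN=fn, FP=fp, TN=n_samples - tp - fn - fp)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedStatisticError(f"{name} is undefined: zero denominator")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN) — recall of the positive class."""
    return _ratio(cm.TP, cm.TP + cm.FN, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    return _ratio(cm.TN, cm.TN + cm.FP, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total — printed as "Precision" in the reference tables."""
    return _ratio(cm.TP + cm.TN, cm.total, "accuracy")


def ppv(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP) — positive predictive value (textbook precision)."""
    return _ratio(cm.TP, cm.TP + cm.FP, "ppv")


def correct_rate(cm: ConfusionMatrix) -> float:
    """Overall accuracy as a percentage (the tables' "Correct" row)."""
    return 100.0 * accuracy(cm)


def pool(cms) -> ConfusionMatrix:
    """Sum counts elementwise over matrices (order-invariant, associative)."""
    cms = list(cms)
    if not cms:
        raise ValueError("pool needs at least one confusion matrix")
    return ConfusionMatrix(
        TP=sum(c.TP for c in cms),
        FN=sum(c.FN for c in cms),
        FP=sum(c.FP for c in cms),
        TN=sum(c.TN for c in cms),
    )


def mean_stat(cms, stat) -> float:
    """Unweighted mean of a per-matrix statistic over matrices."""
    cms = list(cms)
    if not cms:
        raise ValueError("mean_stat needs at least one confusion matrix")
    return float(np.mean([stat(c) for c in cms]))


def roc_points(scores, labels, positive="stress"):
    """Generic ROC curve: (false-positive rate, true-positive rate) arrays.

    Thresholds sweep the distinct score values (predict positive when the
    score is >= threshold), plus the trivial all-negative endpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC needs both classes present")
    fpr, tpr = [0.0], [0.0]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr.append(np.sum(pred & pos) / n_pos)
        fpr.append(np.sum(pred & ~pos) / n_neg)
    return np.asarray(fpr), np.asarray(tpr)


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, matching printed-table rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_reference_tables() -> dict:
    """Load the bundled per-user reference evaluation tables.

    These are the published confusion-matrix counts and printed statistics
    for the wearable-ECG/SCR validation study this package reimplements;
    they serve as regression fixtures for the statistics layer.
    """
    path = resources.files("cwtcardio.data").joinpath("reference_tables.json")
    with path.open() as fh:
        return json.load(fh)


def cm_from_dict(d: dict) -> ConfusionMatrix:
    """Build a matrix from a ``{"tp":..,"fn":..,"fp":..,"tn":..}`` mapping."""
    return ConfusionMatrix(TP=d["tp"], FN=d["fn"], FP=d["fp"], TN=d["tn"])
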