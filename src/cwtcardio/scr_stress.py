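"""Skin-conductance-response stress analysis.

The SCR sensor does not measure skin resistance ``Rs`` directly: the skin
sits in a voltage divider with a fixed resistor ``R2`` (890 kOhm) across
the supply ``Vcc``, and the digitized output is

    Vo = R2 / (Rs + R2) * Vcc.

Sweating under stress lowers ``Rs`` and therefore raises ``Vo``.  Because
baseline skin conductance differs wildly between people, stress-vs-relax
classification is strictly per subject: each user gets their own decision
tree, trained on their labeled samples only, and thresholds are never
shared.  The tree is a C4.5-style binary classifier on continuous features
(instantaneous voltage by default, optionally its first difference), grown
by maximizing the information gain ratio over midpoint thresholds.

Protocol labeling follows the two laboratory stressors: a color-word
interference (Stroop) task, where samples during the task are stress and
the relax reference is the first 55 s or the last 60 s (or a custom span);
and an annoying-sounds session, where only the sounds the subject actually
reacted to are labeled stressful, each over its 15 s response span.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .signal_io import SCR_ADC_RESOLUTION_V, SCR_ADC_VMAX_V, SCRRecord

__all__ = [
    "DividerConfig",
    "ProtocolSchedule",
    "ScheduleError",
    "TrainingError",
    "EvaluationError",
    "StressTree",
    "TreeNode",
    "divider_voltage",
    "resistance_from_voltage",
    "label_samples",
    "extract_features",
    "train_stress_tree",
    "reduced_error_prune",
    "evaluate_tree",
    "STROOP_RELAX_BEGIN_S",
    "STROOP_RELAX_END_S",
]

STROOP_RELAX_BEGIN_S = 55.0   # relax window at the start: first 55 s
STROOP_RELAX_END_S = 60.0     # relax window at the end: last 60 s
SOUND_RESPONSE_S = 15.0       # spacing/response span of the sounds protocol


class ScheduleError(ValueError):
    """Protocol schedule events are contradictory or malformed."""


class TrainingError(ValueError):
    """The labeled data cannot train a classifier."""


class EvaluationError(ValueError):
    """The record carries no usable labels to evaluate against."""


# ---------------------------------------------------------------------------
# Voltage divider
# ---------------------------------------------------------------------------

@dataclass
class DividerConfig:
    """Front-end constants of the SCR board.

    ``Vcc`` is not uniquely pinned down by the published voltage anchors
    (0.136 V at 10 MOhm implies about 1.664 V, 1.755 V at 10 kOhm implies
    about 1.775 V); the default adopts the low-resistance anchor, and the
    field is explicit so either derivation can be configured.
    """

    R2: float = 890e3
    Vcc: float = 1.775
    adc_resolution: float = SCR_ADC_RESOLUTION_V
    adc_vmax: float = SCR_ADC_VMAX_V

    def __post_init__(self) -> None:
        if self.R2 <= 0 or self.Vcc <= 0:
            raise ValueError("R2 and Vcc must be positive")


def divider_voltage(Rs, cfg: DividerConfig | None = None):
    """Divider output ``Vo = R2/(Rs + R2) * Vcc``; decreasing in ``Rs``."""
    cfg = cfg or DividerConfig()
    Rs = np.asarray(Rs, dtype=float)
    if np.any(Rs < 0):
        raise ValueError("skin resistance must be nonnegative")
    out = cfg.R2 / (Rs + cfg.R2) * cfg.Vcc
    return float(out) if out.ndim == 0 else out


def resistance_from_voltage(Vo, cfg: DividerConfig | None = None):
    """Invert the divider: ``Rs = R2 * (Vcc - Vo) / Vo`` for ``0 < Vo <= Vcc``."""
    cfg = cfg or DividerConfig()
    Vo = np.asarray(Vo, dtype=float)
    if np.any(Vo <= 0) or np.any(Vo > cfg.Vcc):
        raise ValueError(f"Vo must lie in (0, Vcc={cfg.Vcc}] V")
    out = cfg.R2 * (cfg.Vcc - Vo) / Vo
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Protocol labeling
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSchedule:
    """Label schedule for a stress protocol.

    ``events`` is a time-ordered list of ``(time_s, label)`` step changes
    with labels in {"stress", "relax", "unlabeled"}: each label applies
    from its time until the next event (or the end of the record).  For the
    Stroop protocol, ``relax_window_choice`` then overrides the relax
    reference: ``"beginning"`` labels [0, 55) s relax, ``"end"`` the last
    60 s, and ``("custom", start, end)`` an arbitrary span (one subject was
    calm only between 15 and 55 s).
    """

    kind: str = "sounds"
    events: list[tuple[float, str]] = field(default_factory=list)
    relax_window_choice: object = "beginning"

    def __post_init__(self) -> None:
        if self.kind not in ("sounds", "stroop"):
            raise ScheduleError(f"unknown protocol kind {self.kind!r}")
        times = [e[0] for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ScheduleError("events must be time-ordered")
        seen: dict[float, str] = {}
        for when, label in self.events:
            if label not in ("stress", "relax", "unlabeled"):
                raise ScheduleError(f"unknown label {label!r} at t={when}")
            if when in seen and seen[when] != label:
                raise ScheduleError(
                    f"contradictory labels {seen[when]!r}/{label!r} at t={when}"
                )
            seen[when] = label

    @classmethod
    def sounds(cls, onsets_s, reactive, response_s: float = SOUND_RESPONSE_S):
        """Sounds protocol: label 15 s response spans of reactive sounds.

        ``onsets_s`` are the sound onset times; ``reactive`` is a boolean
        mask saying which sounds the subject reported a reaction to.  Only
        reactive spans become stress; everything else stays relax.
        """
        events: list[tuple[float, str]] = [(0.0, "relax")]
        for onset, hit in zip(onsets_s, reactive):
            if hit:
                events.append((float(onset), "stress"))
                events.append((float(onset) + response_s, "relax"))
        events.sort(key=lambda e: e[0])
        return cls(kind="sounds", events=events)

    @classmethod
    def stroop(cls, test_start_s: float, test_end_s: float,
               relax_window_choice="beginning"):
        """Stroop protocol: stress during the task, relax per the choice."""
        events = [
            (0.0, "unlabeled"),
            (float(test_start_s), "stress"),
            (float(test_end_s), "unlabeled"),
        ]
        return cls(kind="stroop", events=events,
                   relax_window_choice=relax_window_choice)


def label_samples(scr: SCRRecord, schedule: ProtocolSchedule) -> SCRRecord:
    """Apply a protocol schedule to an SCR record, returning a labeled copy."""
    n = scr.n
    t = scr.time
    labels = np.full(n, "unlabeled", dtype=object)
    for when, label in schedule.events:
        labels[t >= when] = label
    if schedule.kind == "stroop":
        choice = schedule.relax_window_choice
        if choice == "beginning":
            lo, hi = 0.0, STROOP_RELAX_BEGIN_S
        elif choice == "end":
            lo, hi = max(t[-1] - STROOP_RELAX_END_S, 0.0) if n else 0.0, np.inf
        else:
            try:
                tag, lo, hi = choice
            except (TypeError, ValueError):
                raise ScheduleError(
                    "relax_window_choice must be 'beginning', 'end' or "
                    "('custom', start, end)"
                ) from None
            if tag != "custom":
                raise ScheduleError(f"unknown relax window choice {choice!r}")
        relax = (t >= lo) & (t < hi) & (labels != "stress")
        labels[relax] = "relax"
    return SCRRecord(scr.samples.copy(), fs=scr.fs, labels=labels,
                     subject_id=scr.subject_id)


# ---------------------------------------------------------------------------
# Gain-ratio decision tree (C4.5-style)
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Binary split node or leaf of a :class:`StressTree`."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None           # feature <= threshold
    right: "TreeNode | None" = None
    klass: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass, "counts": self.counts}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "class" in d:
            return cls(klass=d["class"], counts=dict(d.get("counts", {})))
        return cls(feature=d["feature"], threshold=d["threshold"],
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


@dataclass
class StressTree:
    """Per-user stress/relax decision tree on continuous SCR features."""

    root: TreeNode
    feature_names: tuple[str, ...] = ("voltage",)
    subject_id: str | None = None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X), dtype=object)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.klass
        return out

    @property
    def root_threshold(self) -> float:
        if self.root.is_leaf:
            raise ValueError("tree is a leaf; no root threshold")
        return float(self.root.threshold)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "feature_names": list(self.feature_names),
                "subject_id": self.subject_id,
                "root": self.root.to_dict(),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "StressTree":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                d = json.load(fh)
        elif isinstance(source, (str, bytes)):
            d = json.loads(source)
        else:
            d = json.load(source)
        return cls(root=TreeNode.from_dict(d["root"]),
                   feature_names=tuple(d["feature_names"]),
                   subject_id=d.get("subject_id"))


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_split(X: np.ndarray, y: np.ndarray, classes: np.ndarray,
                min_leaf: int):
    """Best (feature, threshold) by gain ratio; ties go to the lower
    threshold, then the lower feature index.  Returns None when no split
    has positive information gain or satisfies the leaf-size floor."""
    n = len(y)
    y_idx = np.searchsorted(classes, y)
    parent_counts = np.bincount(y_idx, minlength=len(classes))
    parent_entropy = _entropy(parent_counts)
    best = None  # (gain_ratio, feature, threshold)
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y_idx[order]
        left = np.zeros(len(classes))
        right = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i + 1] <= xs[i]:          # not a class boundary in value
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            child = (n_left * _entropy(left) + n_right * _entropy(right)) / n
            gain = parent_entropy - child
            if gain <= 1e-12:
                continue
            p_l, p_r = n_left / n, n_right / n
            split_info = -(p_l * math.log2(p_l) + p_r * math.log2(p_r))
            ratio = gain / split_info
            threshold = 0.5 * (xs[i] + xs[i + 1])
            if (
                best is None
                or ratio > best[0] + 1e-12
                or (abs(ratio - best[0]) <= 1e-12
                    and (threshold, f) < (best[2], best[1]))
            ):
                best = (ratio, f, threshold)
    return None if best is None else (best[1], best[2])


def _grow(X: np.ndarray, y: np.ndarray, classes: np.ndarray,
          min_leaf: int) -> TreeNode:
    values, counts = np.unique(y, return_counts=True)
    majority = str(values[np.argmax(counts)])
    if len(values) == 1 or len(y) < 2 * min_leaf:
        return TreeNode(klass=majority,
                        counts={str(v): int(c) for v, c in zip(values, counts)})
    split = _best_split(X, y, classes, min_leaf)
    if split is None:
        return TreeNode(klass=majority,
                        counts={str(v): int(c) for v, c in zip(values, counts)})
    f, thr = split
    mask = X[:, f] <= thr
    return TreeNode(
        feature=f,
        threshold=thr,
        left=_grow(X[mask], y[mask], classes, min_leaf),
        right=_grow(X[~mask], y[~mask], classes, min_leaf),
    )


def extract_features(scr: SCRRecord, features=("voltage",)):
    """Feature matrix for the classifier.

    ``voltage`` is the instantaneous divider output; ``slope`` its first
    difference times the sampling rate (V/s, first sample 0).
    """
    cols = []
    for name in features:
        if name == "voltage":
            cols.append(scr.samples)
        elif name == "slope":
            slope = np.zeros_like(scr.samples)
            if scr.n > 1:
                slope[1:] = np.diff(scr.samples) * scr.fs
            cols.append(slope)
        else:
            raise ValueError(f"unknown feature {name!r}")
    return np.column_stack(cols) if cols else np.empty((scr.n, 0))


def train_stress_tree(scr: SCRRecord, features=("voltage",),
                      min_leaf: int = 2) -> StressTree:
    """Train a per-user gain-ratio decision tree on labeled SCR samples.

    Only samples labeled stress or relax participate; both classes must be
    present and the total must reach ``2 * min_leaf``.  Growth is
    deterministic given the data: thresholds are midpoints between sorted
    distinct feature values and ties break toward the lower threshold.
    """
    if scr.labels is None:
        raise TrainingError("record carries no labels")
    mask = np.isin(scr.labels, ("stress", "relax"))
    y = scr.labels[mask].astype(object)
    X = extract_features(scr, features)[mask]
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training needs both stress and relax samples")
    if len(y) < 2 * min_leaf:
        raise TrainingError(
            f"training needs at least {2 * min_leaf} labeled samples"
        )
    root = _grow(X, np.asarray(y), classes, min_leaf)
    return StressTree(root=root, feature_names=tuple(features),
                      subject_id=scr.subject_id)


def reduced_error_prune(tree: StressTree, scr: SCRRecord) -> StressTree:
    """Reduced-error pruning against a labeled validation record.

    Bottom-up, an internal node is collapsed to a majority leaf whenever the
    leaf misclassifies no more validation samples than the subtree does.
    Returns a new tree; the input is untouched.
    """
    if scr.labels is None:
        raise EvaluationError("pruning needs a labeled validation record")
    mask = np.isin(scr.labels, ("stress", "relax"))
    X = extract_features(scr, tree.feature_names)[mask]
    y = scr.labels[mask]

    def errors(node: TreeNode, Xv, yv) -> int:
        if node.is_leaf:
            return int(np.sum(yv != node.klass))
        split = Xv[:, node.feature] <= node.threshold
        return errors(node.left, Xv[split], yv[split]) + errors(
            node.right, Xv[~split], yv[~split]
        )

    def prune(node: TreeNode, Xv, yv) -> TreeNode:
        if node.is_leaf:
            return TreeNode(klass=node.klass, counts=dict(node.counts))
        split = Xv[:, node.feature] <= node.threshold
        new = TreeNode(
            feature=node.feature,
            threshold=node.threshold,
            left=prune(node.left, Xv[split], yv[split]),
            right=prune(node.right, Xv[~split], yv[~split]),
        )
        if len(yv) == 0:
            return new
        values, counts = np.unique(yv, return_counts=True)
        majority = str(values[np.argmax(counts)])
        if int(np.sum(yv != majority)) <= errors(new, Xv, yv):
            return TreeNode(
                klass=majority,
                counts={str(v): int(c) for v, c in zip(values, counts)},
            )
        return new

    return StressTree(root=prune(tree.root, X, y),
                      feature_names=tree.feature_names,
                      subject_id=tree.subject_id)


def evaluate_tree(tree: StressTree, scr: SCRRecord):
    """Per-sample confusion matrix of a tree on a labeled record.

    Stress is the positive class.  Returns a
    :class:`cwtcardio.metrics.ConfusionMatrix`.
    """
    from .metrics import ConfusionMatrix

    if scr.labels is None or not np.isin(scr.labels, ("stress", "relax")).any():
        raise EvaluationError("record carries no stress/relax labels")
    mask = np.isin(scr.labels, ("stress", "relax"))
    y = scr.labels[mask]
    pred = tree.predict(extract_features(scr, tree.feature_names)[mask])
    tp = int(np.sum((y == "stress") & (pred == "stress")))
    fn = int(np.sum((y == "stress") & (pred == "relax")))
    fp = int(np.sum((y == "relax") & (pred == "stress")))
    tn = int(np.sum((y == "relax") & (pred == "relax")))
    return ConfusionMatrix(TP=tp, FN=fn, FP=fp, TN=tn)
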