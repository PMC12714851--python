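"""Confusion-matrix metrics and ROC analysis.

Binary convention: class 1 is the positive class.  Ratios are computed from
the four counts exactly as printed in the classical definitions:

* accuracy     = (T+ + T-) / (T+ + T- + F+ + F-)
* sensitivity  = T+ / (T+ + F-)
* specificity  = T- / (T- + F+)
* precision    = T+ / (T+ + F+)
* F1           = 2 * precision * sensitivity / (precision + sensitivity)

Undefined ratios (zero denominator) are reported as 0.0 with the
``undefined`` flag listing which ones were degenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["Metrics", "evaluate", "roc_auc"]


@dataclass
class Metrics:
    T_pos: int
    T_neg: int
    F_pos: int
    F_neg: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: list[str] = field(default_factory=list)
    per_group: dict[str, "Metrics"] | None = None

    @property
    def n(self) -> int:
        return self.T_pos + self.T_neg + self.F_pos + self.F_neg

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)


def _ratios(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    undefined: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = safe(tp + tn, tp + tn + fp + fn, "accuracy")
    sens = safe(tp, tp + fn, "sensitivity")
    spec = safe(tn, tn + fp, "specificity")
    prec = safe(tp, tp + fp, "precision")
    f1 = safe(2 * prec * sens, prec + sens, "f1")
    return Metrics(tp, tn, fp, fn, acc, sens, spec, prec, f1, undefined)


def evaluate(
    predictions: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
) -> Metrics:
    """Score hard binary predictions against labels.

    ``predictions`` and ``labels`` hold 0/1 class ids.  When ``groups`` is
    given, a per-group breakdown (e.g. demographic splits) is attached.
    """
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    m = _ratios(tp, tn, fp, fn)
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != labels.shape:
            raise ValueError("groups and labels differ in length")
        m.per_group = {
            str(g): evaluate(predictions[groups == g], labels[groups == g])
            for g in np.unique(groups)
        }
    return m


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve and area from a threshold sweep over the unique scores.

    Returns ``(points, auc)`` where ``points`` is an ``(n_thresholds + 2, 2)``
    array of (false-positive rate, true-positive rate) pairs, sorted along
    the sweep, and ``auc`` the trapezoid-rule area.  The area equals the
    probability that a random positive outscores a random negative (ties
    counting one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep one operating point per distinct score (last index of each run)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), scores.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
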