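"""Evaluation computations: precision/recall/F1, accuracy, confusion
matrices, ROC/AUC, and the detection-rate arithmetic used to summarize
diseased/healthy leaf detection.

Detection rates use a truncate-then-complement convention: the false
recognition rate is ``100 * misidentified / total`` truncated to two
decimals, and the correct rate is its exact complement to 100, so the two
always sum to 100.00.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("counts must be a square non-negative matrix")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    def per_class_counts(self, c: int):
        """(TP, FP, FN) for class c in one-vs-rest terms."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        return tp, fp, fn


@dataclass(frozen=True)
class DetectionCounts:
    """Leaf-level detection outcome counts.

    detected_diseased / detected_healthy: totals per true condition;
    diseased_misidentified: diseased leaves assigned any wrong label, of
    which diseased_as_healthy were called healthy (the rest were called a
    different disease); healthy_misidentified: healthy leaves called
    diseased.
    """

    detected_diseased: int
    diseased_misidentified: int
    diseased_as_healthy: int
    detected_healthy: int
    healthy_misidentified: int

    def __post_init__(self):
        if self.diseased_misidentified > self.detected_diseased:
            raise ValueError("misidentified diseased exceeds detected diseased")
        if self.diseased_as_healthy > self.diseased_misidentified:
            raise ValueError("diseased-as-healthy exceeds diseased misidentified")
        if self.healthy_misidentified > self.detected_healthy:
            raise ValueError("misidentified healthy exceeds detected healthy")


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "F1") \
        if (precision + recall) > 0 else 0.0
    return precision, recall, f1


def confusion_and_accuracy(y_true, y_pred, num_classes: int):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= num_classes):
            raise ValueError(f"{name} labels out of range [0, {num_classes})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))
    cm = ConfusionMatrix(counts=counts)
    return cm, cm.accuracy


def macro_f1(cm: ConfusionMatrix):
    """Macro-averaged (precision, recall, F1) over classes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        triples = [precision_recall_f1(*cm.per_class_counts(c))
                   for c in range(cm.counts.shape[0])]
    return tuple(float(np.mean([t[i] for t in triples])) for i in range(3))


def roc_auc(scores, binary_labels) -> float:
    """Area under the ROC curve; ties handled by rank averaging."""
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores)))


def _truncate2(x: float) -> float:
    return math.floor(x * 100.0) / 100.0


def detection_rates(counts: DetectionCounts, round_rates: bool = False) -> dict:
    """Percent rates from detection counts.

    False rates are ``100 * misidentified / total`` truncated to two
    decimals (or rounded with ``round_rates=True``); each correct rate is
    100 minus the corresponding false rate.
    """
    if counts.detected_diseased == 0 or counts.detected_healthy == 0:
        raise ValueError("detection totals must be positive")
    fmt = (lambda x: round(x, 2)) if round_rates else _truncate2
    diseased_false = fmt(100.0 * counts.diseased_misidentified / counts.detected_diseased)
    healthy_false = fmt(100.0 * counts.healthy_misidentified / counts.detected_healthy)
    as_healthy = fmt(100.0 * counts.diseased_as_healthy / counts.detected_diseased)
    as_other = fmt(100.0 * (counts.diseased_misidentified - counts.diseased_as_healthy)
                   / counts.detected_diseased)
    return {
        "diseased_false_rate": diseased_false,
        "diseased_correct_rate": round(100.0 - diseased_false, 2),
        "diseased_as_healthy_rate": as_healthy,
        "diseased_as_other_disease_rate": as_other,
        "healthy_false_rate": healthy_false,
        "healthy_correct_rate": round(100.0 - healthy_false, 2),
    }
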