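"""Confusion-matrix construction and the derived scalar metrics.

Cobra is the positive class throughout. Metrics are returned as fractions;
formatting as percentages happens only at the CLI/report layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .synthetic_data import COBRA, LABELS


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise EvaluationError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(true_labels: Sequence[str],
              predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with cobra as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError(
            f"label sequences differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}")
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in LABELS:
            raise EvaluationError(f"unknown label {lab!r}")
    tp = fn = fp = tn = 0
    for truth, pred in zip(true_labels, predicted_labels):
        if truth == COBRA:
            if pred == COBRA:
                tp += 1
            else:
                fn += 1
        else:
            if pred == COBRA:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    if cm.tp + cm.fn < 1:
        raise EvaluationError("sensitivity undefined: no positive cases")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    if cm.tn + cm.fp < 1:
        raise EvaluationError("specificity undefined: no negative cases")
    return cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    if cm.total < 1:
        raise EvaluationError("accuracy undefined: empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def auc(scores: Sequence[float], true_labels: Sequence[str]) -> float:
    """Probability that a random positive outscores a random negative.

    Computed with the rank (Mann-Whitney) formula; tied scores count 0.5
    per positive-negative pair.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(true_labels):
        raise EvaluationError("scores and labels differ in length")
    positives = np.array([lab == COBRA for lab in true_labels])
    n_pos, n_neg = int(positives.sum()), int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 per pair
    rank_sum = ranks[positives].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_report(cm: ConfusionMatrix,
                   scores: Sequence[float] | None = None,
                   true_labels: Sequence[str] | None = None) -> dict:
    """Bundle the scalar metrics into a JSON-ready dict (fractions)."""
    report = {
        "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "accuracy": accuracy(cm),
    }
    if scores is not None and true_labels is not None:
        report["auc"] = auc(scores, true_labels)
    return report
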