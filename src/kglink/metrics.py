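"""Evaluation metrics on explicit confusion tables.

Balanced accuracy is the mean of per-class recall, which is insensitive to
class imbalance -- the natural choice when 81 node types span four orders of
magnitude in frequency.  For binary tasks it equals the mean of the accuracy
on positives and the accuracy on negatives.  F1 scores (per-class, macro and
support-weighted) complement it for the edge-prediction reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionTable", "balanced_accuracy", "f1_scores"]


@dataclass
class ConfusionTable:
    """k x k confusion matrix; rows = true class, columns = predicted class."""

    matrix: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape must match number of labels")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: Sequence, y_pred: Sequence,
                         labels: Sequence | None = None) -> "ConfusionTable":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = np.unique(np.concatenate([y_true, y_pred]))
        labels = list(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(m, labels)

    @property
    def support(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def balanced_accuracy(ct: ConfusionTable) -> float:
    """Mean of per-class recall; zero-support classes excluded with a warning."""
    support = ct.support
    if ct.matrix.sum() == 0:
        raise ValueError("confusion table is all zero")
    if (support == 0).any():
        empty = [ct.labels[i] for i in np.flatnonzero(support == 0)]
        warnings.warn(f"classes with zero support excluded from recall: {empty}")
    keep = support > 0
    recalls = np.diag(ct.matrix)[keep] / support[keep]
    return float(recalls.mean())


def f1_scores(ct: ConfusionTable) -> tuple[np.ndarray, float, float]:
    """Per-class, macro and support-weighted F1.

    A class with ``precision + recall == 0`` (e.g. never predicted and never
    recalled) gets F1 = 0 by convention.  Returns ``(per_class, macro,
    weighted)`` with per-class entries ordered like ``ct.labels``.
    """
    if ct.matrix.sum() == 0:
        raise ValueError("confusion table is all zero")
    diag = np.diag(ct.matrix).astype(float)
    support = ct.support.astype(float)
    predicted = ct.matrix.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(support > 0, diag / support, 0.0)
        precision = np.where(predicted > 0, diag / predicted, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    macro = float(f1.mean())
    weighted = float((f1 * support).sum() / support.sum())
    return f1, macro, weighted
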