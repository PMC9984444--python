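"""Scoring primitives for probabilistic binary classifiers.

Three metrics, matching the usual model-comparison table for toxicity
prediction: Brier score (mean squared error of the predicted probability —
a strictly proper scoring rule, robust to probabilities of exactly 0 or 1),
ROC-AUC (the Mann-Whitney rank statistic: probability a random positive is
scored above a random negative, ties counted one half), and thresholded
classification accuracy.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import brier_score_loss, roc_auc_score


class MetricError(ValueError):
    """Invalid inputs for a metric (empty, out of range, single class...)."""


def _validated(probabilities, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 1 or y.ndim != 1 or p.size != y.size:
        raise MetricError("probabilities and labels must be 1-d of equal length")
    if p.size == 0:
        raise MetricError("empty predictions")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise MetricError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise MetricError("labels must be binary 0/1")
    return p, y.astype(int)


@dataclasses.dataclass(frozen=True)
class ScoredPredictions:
    """Paired predicted probabilities and binary labels for one split."""

    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        p, y = _validated(self.probabilities, self.labels)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "labels", y)

    def brier(self) -> float:
        return brier(self.probabilities, self.labels)

    def roc_auc(self) -> float:
        return roc_auc(self.probabilities, self.labels)

    def accuracy(self, threshold: float = 0.5) -> float:
        return accuracy(self.probabilities, self.labels, threshold=threshold)


def brier(probabilities, labels) -> float:
    """Mean of (p - y)^2; 0 is perfect, 0.25 is the constant-half predictor."""
    p, y = _validated(probabilities, labels)
    return float(brier_score_loss(y, p))


def roc_auc(probabilities, labels) -> float:
    """Mann-Whitney ROC-AUC with ties counted one half.

    Raises :class:`MetricError` when only one class is present (the rank
    statistic is undefined).
    """
    p, y = _validated(probabilities, labels)
    if y.min() == y.max():
        raise MetricError("ROC-AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, p))


def accuracy(probabilities, labels, threshold: float = 0.5) -> float:
    """Fraction of patients where (p >= threshold) matches the label.

    Ties at the threshold are classed positive.
    """
    p, y = _validated(probabilities, labels)
    return float(np.mean((p >= threshold).astype(int) == y))
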