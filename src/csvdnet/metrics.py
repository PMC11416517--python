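"""Formula-level binary classification metrics.

Accuracy, precision and recall are computed from the confusion counts;
AUC is the area under the ROC curve, computed as the Mann-Whitney rank
statistic (fraction of positive/negative pairs correctly ordered, ties
counted 1/2 — the two are equivalent); BCE is the mean binary
cross-entropy in nats with probabilities clipped to [eps, 1-eps].

Ratios with a zero denominator (e.g. precision with no positive
predictions) are reported as None, never silently as zero, so fold
averages are not corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

BCE_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: Optional[float]
    auc: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    bce_loss: Optional[float]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "bce_loss": self.bce_loss,
        }


def _validate(y_true, y_prob) -> tuple:
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_prob, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} scores")
    if y.size < 1:
        raise ValueError("need at least one sample")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    return y, p


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; prediction is positive iff prob >= threshold."""
    y, p = _validate(y_true, y_prob)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> Optional[float]:
    return None if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> Optional[float]:
    return None if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)


def auc(y_true, y_prob) -> Optional[float]:
    """Area under the ROC curve via the rank statistic.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties counted 1/2.  Undefined (None)
    when either class is absent.
    """
    y, p = _validate(y_true, y_prob)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(p)  # average ranks implement the tie-1/2 convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bce(y_true, y_prob, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy in nats per sample (clipped probabilities)."""
    y, p = _validate(y_true, y_prob)
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def metric_suite(counts: ConfusionCounts, y_true=None, y_prob=None) -> MetricsReport:
    """Assemble the full report from counts plus (optionally) raw scores
    for the threshold-free quantities (AUC, BCE)."""
    a = u = b = None
    if y_true is not None and y_prob is not None:
        u = auc(y_true, y_prob)
        b = bce(y_true, y_prob)
    return MetricsReport(
        accuracy=accuracy(counts),
        auc=u,
        precision=precision(counts),
        recall=recall(counts),
        bce_loss=b,
    )


def evaluate(y_true, y_prob, threshold: float = 0.5) -> MetricsReport:
    """One-call evaluation: confusion at ``threshold`` plus AUC and BCE."""
    return metric_suite(confusion(y_true, y_prob, threshold), y_true, y_prob)
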