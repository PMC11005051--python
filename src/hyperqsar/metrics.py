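"""Evaluation metrics with explicit tie and degenerate-case conventions.

- ``mcc``: 2x2 contingency closed form; any zero marginal yields 0.
- ``auc``: Mann-Whitney rank statistic with midranks for ties.
- ``concordance_index``: pairs ordered by true value; tied predictions count
  one half; pairs with tied true values are excluded from the normalizer.
- ``roc_enrichment``: TPR / FPR at the smallest score cutoff whose FPR
  reaches the requested level (no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionSet",
    "UndefinedMetricError",
    "mcc",
    "auc",
    "concordance_index",
    "roc_enrichment",
    "mse_mae",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. a single class present)."""


@dataclass
class PredictionSet:
    """True values paired with predicted scores."""

    true_values: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.true_values = np.asarray(self.true_values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.true_values.shape != self.scores.shape:
            raise ValueError("true_values and scores must have equal length")
        if not (np.all(np.isfinite(self.true_values)) and np.all(np.isfinite(self.scores))):
            raise ValueError("non-finite entries in prediction set")

    @property
    def n(self) -> int:
        return self.true_values.size


def _check_binary(labels: np.ndarray, name: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError(f"{name} must be binary 0/1")
    return labels


def mcc(labels, predicted_labels) -> float:
    """Matthews correlation coefficient; returns 0 when a marginal is zero."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    tp = float(np.sum((y == 1) & (p == 1)))
    tn = float(np.sum((y == 0) & (p == 0)))
    fp = float(np.sum((y == 0) & (p == 1)))
    fn = float(np.sum((y == 1) & (p == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc(labels, scores) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney statistic."""
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("auc requires both classes present")
    ranks = rankdata(s)  # midranks for ties
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def concordance_index(true_values, scores) -> float:
    """Fraction of true-value-ordered pairs whose predictions preserve order.

    Tied predictions contribute 1/2; pairs with equal true values do not
    count toward the normalizer.  Raises when no comparable pair exists.
    """
    d = np.asarray(true_values, dtype=float)
    b = np.asarray(scores, dtype=float)
    if d.shape != b.shape or d.size == 0:
        raise ValueError("inputs must be non-empty vectors of equal length")
    # ordered pairs (i, j) with d[i] > d[j]
    gt = d[:, None] > d[None, :]
    z = int(gt.sum())
    if z == 0:
        raise UndefinedMetricError("all true values equal: concordance undefined")
    diff = b[:, None] - b[None, :]
    wins = float(np.sum(gt & (diff > 0)))
    ties = float(np.sum(gt & (diff == 0)))
    return (wins + 0.5 * ties) / z


def roc_enrichment(labels, scores, fpr_threshold: float) -> float:
    """TPR divided by FPR at the first score cutoff reaching the FPR level.

    Cutoffs sweep from high score to low; a sample is called positive when
    its score is >= the cutoff.  No interpolation: the cutoff used is the
    first one whose FPR is >= ``fpr_threshold``.
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if not 0.0 < fpr_threshold < 1.0:
        raise ValueError("fpr_threshold must lie in (0, 1)")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc_enrichment requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse tied scores: only positions where the cutoff actually changes
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp[last_of_tie]
    fp = fp[last_of_tie]
    fpr = fp / n_neg
    idx = np.searchsorted(fpr, fpr_threshold, side="left")
    if idx == fpr.size:  # cannot happen: last fpr == 1
        idx = fpr.size - 1
    tpr = tp[idx] / n_pos
    return float(tpr / fpr_threshold)


def mse_mae(true_values, predictions) -> tuple[float, float]:
    d = np.asarray(true_values, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if d.shape != p.shape or d.size == 0:
        raise ValueError("inputs must be non-empty vectors of equal length")
    resid = p - d
    return float(np.mean(resid**2)), float(np.mean(np.abs(resid)))
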