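"""Discrimination metrics: AUC and the true skill statistic (TSS).

AUC is the probability that a randomly chosen presence outscores a randomly
chosen absence, ties counting one half — computed here from midranks, which is
algebraically identical to exhaustive pairwise counting. TSS is
``sensitivity + specificity - 1`` maximised over a fixed grid of thresholds;
the grid (101 points on [0, 1], ties resolved to the smallest threshold) is
pinned so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc", "tss", "TssResult", "confusion", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and only one is present."""


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    ranks = rankdata(scores)  # midranks
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) classifying ``score >= threshold`` as presence."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(((labels == 1) & pred).sum())
    fn = int(((labels == 1) & ~pred).sum())
    tn = int(((labels == 0) & ~pred).sum())
    fp = int(((labels == 0) & pred).sum())
    return tp, fn, tn, fp


@dataclass
class TssResult:
    tss: float
    threshold: float
    sensitivity: float
    specificity: float


def tss(scores, labels, thresholds=None) -> TssResult:
    """Maximum TSS over a threshold grid (default: 101 points on [0, 1]).

    Reports the argmax threshold, taking the smallest threshold on ties.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    pred = scores[:, None] >= thresholds[None, :]
    sens = pred[pos].mean(axis=0)
    spec = (~pred[neg]).mean(axis=0)
    values = sens + spec - 1.0
    best = int(np.argmax(values))  # first occurrence = smallest threshold
    return TssResult(float(values[best]), float(thresholds[best]),
                     float(sens[best]), float(spec[best]))
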