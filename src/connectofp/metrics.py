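"""Fingerprinting as binary classification of pair distances.

The labeled distance matrix splits into within-subject (intra) and
between-subject (inter) ordered off-diagonal entries — for the 9-subject x
10-session resting design these number 810 and 7,200, a roughly 90/10
imbalance. A threshold theta declares a pair same-subject when d < theta
(strict); sweeping theta yields accuracy, ROC and precision-recall curves.

The ROC is the parametric curve (inter-CDF(theta), intra-CDF(theta)) over
all distinct pooled distances; trapezoidal integration over that grid gives
the Mann-Whitney statistic with half credit for ties, so identical
intra/inter multisets score exactly 0.5 and perfect separation scores 1.
PR area uses right-continuous step integration (average precision), whose
chance floor is the intra-class prevalence. Delta = min(inter) - max(intra)
is positive exactly when some theta separates the classes perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "PairPartition",
    "ClassifierResult",
    "split_intra_inter",
    "accuracy_curve",
    "roc_curve",
    "pr_curve",
    "separability_delta",
    "classifier_result",
]


@dataclass
class PairPartition:
    """Ordered off-diagonal distances split by subject equality."""

    intra: np.ndarray
    inter: np.ndarray

    def __post_init__(self) -> None:
        self.intra = np.asarray(self.intra, dtype=float).ravel()
        self.inter = np.asarray(self.inter, dtype=float).ravel()

    @property
    def prevalence(self) -> float:
        """Fraction of pairs in the intra (positive) class."""
        total = self.intra.size + self.inter.size
        return self.intra.size / total if total else float("nan")


@dataclass
class ClassifierResult:
    """Threshold sweep plus scalar summaries of a fingerprinting run."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    acc: np.ndarray
    auc_roc: float
    auc_pr: float
    max_acc: float
    argmax_theta: float
    delta: float


def split_intra_inter(d: DistanceMatrix) -> PairPartition:
    """Partition ordered off-diagonal entries by subject equality of the
    row and column labels."""
    subjects = np.asarray(d.subjects)
    same = subjects[:, None] == subjects[None, :]
    off = ~np.eye(d.m, dtype=bool)
    return PairPartition(intra=d.values[same & off], inter=d.values[~same & off])


def _check_nonempty(p: PairPartition, need_inter: bool = True) -> None:
    if p.intra.size == 0:
        raise ValueError("no intra-subject pairs (need >= 2 sessions per subject)")
    if need_inter and p.inter.size == 0:
        raise ValueError("no inter-subject pairs (need >= 2 subjects)")


def _threshold_grid(p: PairPartition) -> np.ndarray:
    pooled = np.unique(np.concatenate([p.intra, p.inter]))
    return np.concatenate([[-np.inf], pooled, [np.inf]])


def _cdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fraction of values strictly below each grid point (d < theta rule)."""
    return np.searchsorted(np.sort(values), grid, side="left") / values.size


def accuracy_curve(
    p: PairPartition, theta_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ACC(theta) = (TP + TN) / all pairs over the grid; returns
    (grid, acc, max_acc, argmax_theta)."""
    _check_nonempty(p)
    grid = _threshold_grid(p) if theta_grid is None else np.asarray(theta_grid, float)
    tp = _cdf(p.intra, grid) * p.intra.size
    fp = _cdf(p.inter, grid) * p.inter.size
    tn = p.inter.size - fp
    acc = (tp + tn) / (p.intra.size + p.inter.size)
    k = int(np.argmax(acc))
    return grid, acc, float(acc[k]), float(grid[k])


def roc_curve(p: PairPartition) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(thresholds, fpr, tpr, auc); the curve is the inter-CDF against the
    intra-CDF, and the trapezoidal area equals the tie-aware Mann-Whitney
    statistic."""
    _check_nonempty(p)
    grid = _threshold_grid(p)
    tpr = _cdf(p.intra, grid)
    fpr = _cdf(p.inter, grid)
    auc = float(np.trapezoid(tpr, fpr))
    return grid, fpr, tpr, auc


def pr_curve(p: PairPartition) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(thresholds, recall, precision, auc_pr) with step integration;
    precision at zero predicted positives is taken as 1."""
    _check_nonempty(p)
    grid = _threshold_grid(p)
    tp = _cdf(p.intra, grid) * p.intra.size
    fp = _cdf(p.inter, grid) * p.inter.size
    predicted = tp + fp
    precision = np.where(predicted > 0, tp / np.maximum(predicted, 1e-300), 1.0)
    recall = tp / p.intra.size
    auc_pr = float(np.sum(np.diff(recall) * precision[1:]))
    return grid, recall, precision, auc_pr


def separability_delta(p: PairPartition) -> float:
    """Smallest between-subject minus largest within-subject distance;
    positive iff a threshold separates the classes perfectly."""
    _check_nonempty(p)
    return float(p.inter.min() - p.intra.max())


def classifier_result(p: PairPartition) -> ClassifierResult:
    """Full threshold sweep on the shared grid of distinct pooled distances."""
    grid, fpr, tpr, auc_roc = roc_curve(p)
    _, recall, precision, auc_pr = pr_curve(p)
    _, acc, max_acc, argmax_theta = accuracy_curve(p, grid)
    return ClassifierResult(
        thresholds=grid,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=recall,
        acc=acc,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
        max_acc=max_acc,
        argmax_theta=argmax_theta,
        delta=separability_delta(p),
    )
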