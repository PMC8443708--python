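"""Diagnostic evaluation statistics for compression-ultrasound DVT classification.

Implements the evaluation toolbox used throughout the package: F1 for
categorical labels, per-label Sørensen-Dice for segmentation masks,
bounding-box IoU (with the set-IoU ``F1/(2-F1)`` identity), sensitivity /
specificity / accuracy, prevalence-adjusted predictive values, ROC curves
with trapezoidal AUC and Youden-optimal thresholds, normal-approximation
confidence intervals across cross-validation folds, and a noncentral-t
power analysis for two-sample comparisons.

Undefined metrics (e.g. Dice on a label absent from both masks) raise
:class:`UndefinedMetricError` instead of silently returning 0, so per-label
averages cannot be biased by degenerate entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "FoldResults",
    "UndefinedMetricError",
    "f1_score",
    "dice",
    "bbox_iou",
    "set_iou",
    "sens_spec_acc",
    "ppv_npv_adjusted",
    "roc_auc",
    "optimal_threshold",
    "fold_ci",
    "power_min_n",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (empty class, absent label...)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (classifications or pixels, per context)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """An ROC curve as ordered (threshold, FPR, TPR) points plus its AUC.

    Points run from the strictest threshold (no positives called) to the
    loosest; FPR and TPR are non-decreasing from (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class FoldResults:
    """Per-fold metric values with a normal-approximation summary CI."""

    values: np.ndarray
    mean: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    n_folds: int = field(default=0)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def f1_score(c: ConfusionCounts) -> float:
    """F1 = TP / (TP + (FP + FN) / 2)."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        raise UndefinedMetricError("F1 undefined when tp = fp = fn = 0")
    return c.tp / denom


def _label_counts(pred: np.ndarray, true: np.ndarray, label: int) -> tuple[int, int, int]:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    p = pred == label
    t = true == label
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, fn


def dice(pred: np.ndarray, true: np.ndarray, label: int) -> float:
    """Per-label Sørensen-Dice coefficient: 2 TP / (2 TP + FP + FN)."""
    tp, fp, fn = _label_counts(pred, true, label)
    if tp + fp + fn == 0:
        raise UndefinedMetricError(
            f"Dice undefined: label {label} absent from both masks"
        )
    return 2 * tp / (2 * tp + fp + fn)


def set_iou(pred: np.ndarray, true: np.ndarray, label: int) -> float:
    """Pixel-set Jaccard index for ``label``; equals Dice / (2 - Dice)."""
    tp, fp, fn = _label_counts(pred, true, label)
    if tp + fp + fn == 0:
        raise UndefinedMetricError(
            f"IoU undefined: label {label} absent from both masks"
        )
    return tp / (tp + fp + fn)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return int(r0), int(r1) + 1, int(c0), int(c1) + 1  # half-open


def bbox_iou(pred: np.ndarray, true: np.ndarray, label: int) -> float:
    """IoU of the axis-aligned bounding boxes of ``label`` in the two masks."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    p = pred == label
    t = true == label
    if not p.any() or not t.any():
        raise UndefinedMetricError(
            f"bounding-box IoU undefined: label {label} absent from a mask"
        )
    pr0, pr1, pc0, pc1 = _bbox(p)
    tr0, tr1, tc0, tc1 = _bbox(t)
    ih = max(0, min(pr1, tr1) - max(pr0, tr0))
    iw = max(0, min(pc1, tc1) - max(pc0, tc0))
    inter = ih * iw
    area_p = (pr1 - pr0) * (pc1 - pc0)
    area_t = (tr1 - tr0) * (tc1 - tc0)
    union = area_p + area_t - inter
    return inter / union


def sens_spec_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from binary confusion counts."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    return sens, spec, acc


def ppv_npv_adjusted(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Predictive values at an externally supplied population prevalence.

    Bayes' rule on the 2x2 table: PPV = s·π / (s·π + (1-sp)(1-π)) and
    NPV = sp·(1-π) / (sp·(1-π) + (1-s)·π).  Used when the case-control mix
    of a validation set does not reflect the clinical population (e.g. a
    DVT clinic prevalence of 7.1% against an enriched study set).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    s, sp, pi = sensitivity, specificity, prevalence
    ppv_den = s * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - s) * pi
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedMetricError("predictive value denominator is zero")
    return s * pi / ppv_den, sp * (1 - pi) / npv_den


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve by threshold sweep over unique scores, AUC by trapezoid rule.

    Equal scores are grouped into a single threshold so ties move the
    operating point diagonally, which makes the trapezoidal AUC equal the
    Mann-Whitney concordance probability (ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # group ties: keep the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(curve: ROCCurve) -> float:
    """Threshold maximizing Youden's J = TPR - FPR; ties favour sensitivity.

    Among points with equal J the one with the higher TPR (hence a looser,
    more sensitive threshold) is returned.
    """
    j = curve.tpr - curve.fpr
    best = np.flatnonzero(j == j.max())
    # higher TPR wins ties; sweep order guarantees TPR is non-decreasing
    idx = best[np.argmax(curve.tpr[best])]
    thr = curve.thresholds[idx]
    return float(thr)


# ---------------------------------------------------------------------------
# Cross-validation summaries and power analysis
# ---------------------------------------------------------------------------

def fold_ci(
    per_fold_values: Sequence[float],
    level: float = 0.95,
    truncate_unit: bool = True,
) -> FoldResults:
    """Mean and normal-approximation CI across cross-validation folds.

    CI = mean ± z(level) · sd / sqrt(k) with the sample standard deviation
    (ddof=1).  Rates are truncated to [0, 1] when ``truncate_unit``.
    """
    values = np.asarray(per_fold_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("fold_ci requires at least 2 fold values")
    k = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * sd / math.sqrt(k)
    lo, hi = mean - half, mean + half
    if truncate_unit:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return FoldResults(values=values, mean=mean, ci_lower=lo, ci_upper=hi,
                       level=level, n_folds=k)


def _t_test_power(n: int, d: float, alpha: float, sides: int) -> float:
    """Power of a two-sample t-test with n per group via the noncentral t."""
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    if sides == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def power_min_n(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    sides: int = 1,
    test_type: str = "two_sample",
    max_n: int = 1_000_000,
) -> int:
    """Smallest per-group n at which a t-test reaches the requested power.

    Uses the noncentral-t distribution of the test statistic under the
    alternative (effect size ``d`` = standardized mean difference), iterating
    n upward from 2.  The default is a one-sided two-sample comparison.
    ``test_type='one_sample'`` uses df = n - 1 and ncp = d·sqrt(n).
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if test_type not in ("two_sample", "one_sample"):
        raise ValueError(f"unknown test_type {test_type!r}")

    for n in range(2, max_n + 1):
        if test_type == "two_sample":
            p = _t_test_power(n, d, alpha, sides)
        else:
            df = n - 1
            ncp = d * math.sqrt(n)
            if sides == 1:
                crit = stats.t.ppf(1 - alpha, df)
                p = float(stats.nct.sf(crit, df, ncp))
            else:
                crit = stats.t.ppf(1 - alpha / 2, df)
                p = float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
        if p >= power:
            return n
    raise RuntimeError(f"requested power {power} not reached by n = {max_n}")
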