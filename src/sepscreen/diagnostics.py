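"""Diagnostic-accuracy engine.

Confusion matrices, the five screening metrics (sensitivity, specificity,
PPV, NPV, accuracy) with Clopper-Pearson exact 95% binomial intervals,
ROC curves with trapezoidal AUC, DeLong or stratified-bootstrap AUC
intervals, and reconstruction of a confusion matrix from published summary
sensitivity/specificity and group sizes (which lets a printed accuracy
table be reproduced down to its rounded percentages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .types import ValidationError

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    endpoint: str = ""
    rule: str = ""

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    name: str
    point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    numerator: int
    denominator: int
    defined: bool = True
    method: str = "Clopper-Pearson exact"
    alpha: float = 0.05

    @property
    def percent(self) -> Optional[int]:
        """Point estimate as a whole percentage, round half up."""
        return None if self.point is None else round_half_up(100 * self.point)

    @property
    def ci_percent(self) -> Optional[tuple[int, int]]:
        if self.ci_low is None:
            return None
        return round_half_up(100 * self.ci_low), round_half_up(100 * self.ci_high)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def confusion(labels: Sequence[bool], predictions: Sequence[bool],
              endpoint: str = "", rule: str = "") -> ConfusionMatrix:
    """Exact 2x2 counts for one positivity rule against one endpoint."""
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.size == 0 or y.shape != p.shape:
        raise ValidationError("labels and predictions must be equal-length and non-empty")
    return ConfusionMatrix(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
        tn=int(np.sum(~y & ~p)),
        endpoint=endpoint,
        rule=rule,
    )


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval from beta quantiles."""
    if not (0 <= successes <= n) or n < 1:
        raise ValidationError(f"invalid counts: successes={successes}, n={n}")
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def _estimate(name: str, numerator: int, denominator: int, alpha: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(name=name, point=None, ci_low=None, ci_high=None,
                              numerator=numerator, denominator=0, defined=False, alpha=alpha)
    low, high = clopper_pearson(numerator, denominator, alpha)
    return MetricEstimate(name=name, point=numerator / denominator, ci_low=low,
                          ci_high=high, numerator=numerator, denominator=denominator,
                          alpha=alpha)


def metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> dict[str, MetricEstimate]:
    """The five screening metrics with exact binomial 95% CIs.

    A metric with a zero denominator is returned flagged as undefined
    rather than propagating NaN.
    """
    return {
        "sensitivity": _estimate("sensitivity", cm.tp, cm.tp + cm.fn, alpha),
        "specificity": _estimate("specificity", cm.tn, cm.tn + cm.fp, alpha),
        "ppv": _estimate("ppv", cm.tp, cm.tp + cm.fp, alpha),
        "npv": _estimate("npv", cm.tn, cm.tn + cm.fn, alpha),
        "accuracy": _estimate("accuracy", cm.tp + cm.tn, cm.n, alpha),
    }


def reconstruct_confusion(sens: float, spec: float, n_pos: int, n_neg: int,
                          endpoint: str = "", rule: str = "") -> ConfusionMatrix:
    """Rebuild the 2x2 table behind published sensitivity/specificity.

    tp and tn are round-half-up of sens*n_pos and spec*n_neg; fn and fp are
    the complements, so the group sizes are preserved exactly.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValidationError("sens and spec must be proportions in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("group sizes must be >= 1")
    tp = round_half_up(sens * n_pos)
    tn = round_half_up(spec * n_neg)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn,
                           endpoint=endpoint, rule=rule)


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray     # descending cut-offs (first entry +inf)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_low: Optional[float] = None
    auc_ci_high: Optional[float] = None
    ci_method: Optional[str] = None
    endpoint: str = ""
    score_name: str = ""


def roc(scores: Sequence[float], labels: Sequence[bool],
        endpoint: str = "", score_name: str = "") -> RocCurve:
    """ROC curve over the distinct observed score values, with trapezoidal AUC.

    The positivity rule at threshold t is score >= t; the trapezoidal AUC
    equals the tie-corrected Mann-Whitney statistic U/(n_pos*n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size == 0 or s.shape != y.shape:
        raise ValidationError("scores and labels must be equal-length and non-empty")
    if y.all() or (~y).all():
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    endpoint=endpoint, score_name=score_name)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, variance) via DeLong's placement-value decomposition."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa, with ties at 1/2
    v10 = np.empty(m)
    v01 = np.empty(n)
    order = np.argsort(neg, kind="mergesort")
    sorted_neg = neg[order]
    lt = np.searchsorted(sorted_neg, pos, side="left")
    le = np.searchsorted(sorted_neg, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    order = np.argsort(pos, kind="mergesort")
    sorted_pos = pos[order]
    gt = m - np.searchsorted(sorted_pos, neg, side="right")
    ge = m - np.searchsorted(sorted_pos, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores: Sequence[float], labels: Sequence[bool],
           method: str = "delong", alpha: float = 0.05,
           n_boot: int = 2000, seed: int = 0) -> tuple[float, float, str]:
    """95% CI for the ROC AUC.

    ``method`` is "delong" (variance-based, default) or "bootstrap"
    (stratified, seeded). A degenerate DeLong variance falls back to the
    bootstrap with a warning. The interval is clipped to [0, 1]. Returns
    (low, high, method_used).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise ValidationError("AUC CI requires both classes present")
    if method == "delong":
        auc, var = _delong_variance(s, y)
        if var > 0:
            z = stats.norm.ppf(1 - alpha / 2)
            half = z * math.sqrt(var)
            return max(0.0, auc - half), min(1.0, auc + half), "delong"
        import warnings
        warnings.warn("degenerate DeLong variance; falling back to stratified bootstrap")
        method = "bootstrap"
    if method != "bootstrap":
        raise ValidationError(f"unknown AUC CI method: {method}")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, neg_idx.size, replace=True)
        auc_b, _ = _delong_variance(np.concatenate([s[pi], s[ni]]),
                                    np.concatenate([np.ones(pi.size, bool),
                                                    np.zeros(ni.size, bool)]))
        aucs[b] = auc_b
    low, high = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high), "bootstrap"


def roc_with_ci(scores: Sequence[float], labels: Sequence[bool],
                endpoint: str = "", score_name: str = "",
                method: str = "delong", seed: int = 0) -> RocCurve:
    """ROC curve with its AUC confidence interval attached."""
    curve = roc(scores, labels, endpoint=endpoint, score_name=score_name)
    low, high, used = auc_ci(scores, labels, method=method, seed=seed)
    return RocCurve(thresholds=curve.thresholds, tpr=curve.tpr, fpr=curve.fpr,
                    auc=curve.auc, auc_ci_low=low, auc_ci_high=high,
                    ci_method=used, endpoint=endpoint, score_name=score_name)
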