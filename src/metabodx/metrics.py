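"""Diagnostic metrics: ROC curves, top-left threshold selection,
confusion-derived panels, Wilson score intervals, Fisher exact tests and
Z-statistic comparisons.

Score orientation is fixed package-wide: the positive class has the higher
discriminant score, and a sample is called positive when score >= threshold.
Report-style percentages round half-up to the nearest integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, ValidationError


def round_half_up_percent(x: float) -> int:
    """0.715 -> 72; matches clinical-report rounding."""
    return int(math.floor(100.0 * x + 0.5))


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    """ROC curve over the distinct observed scores (plus a +inf endpoint).

    ``thresholds`` descend; point i is the operating point "positive if
    score >= thresholds[i]".  The curve runs from (0, 0) to (1, 1) and
    ``auc`` is the trapezoidal area, equal to the Mann-Whitney U statistic
    over n+ x n- pairs with half credit for ties.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def roc_curve(scores, labels) -> RocCurve:
    """Build a ROC curve from discriminant scores and binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise ValidationError("scores and labels length mismatch")
    pos = labels == np.max(labels) if labels.dtype != bool else labels
    if pos.all() or (~pos).all():
        raise DataError("ROC needs both classes present")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    p_sorted = pos[order].astype(int)
    # indices where a tie group of equal scores ends
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tps = np.cumsum(p_sorted)[distinct]
    fps = (distinct + 1) - tps
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    scores=scores.copy(), labels=pos.astype(int))


def optimal_threshold_topleft(roc: RocCurve) -> float:
    """Threshold of the ROC point closest (Euclidean) to the top-left corner.

    Ties break toward higher specificity, then toward the higher threshold.
    """
    d2 = (1.0 - roc.tpr) ** 2 + roc.fpr ** 2
    best = d2.min()
    cand = np.flatnonzero(d2 <= best + 1e-12)
    # higher specificity = lower fpr; fpr is nondecreasing along the curve
    cand = cand[roc.fpr[cand] == roc.fpr[cand].min()]
    return float(np.max(roc.thresholds[cand]))


# ---------------------------------------------------------------------------
# confusion counts


@dataclass
class ConfusionCounts:
    """2x2 contingency counts for a binary classifier."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, labels01, pred01) -> "ConfusionCounts":
        labels01 = np.asarray(labels01).astype(int)
        pred01 = np.asarray(pred01).astype(int)
        return cls(
            tp=int(np.sum((labels01 == 1) & (pred01 == 1))),
            fp=int(np.sum((labels01 == 0) & (pred01 == 1))),
            fn=int(np.sum((labels01 == 1) & (pred01 == 0))),
            tn=int(np.sum((labels01 == 0) & (pred01 == 0))),
        )


def confusion_panel(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV, NPV, accuracy, balanced accuracy and
    F1 from a 2x2 table; metrics with a zero denominator come back NaN and
    are listed under ``undefined``."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    panel = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(c.tp, c.tp + c.fp, "ppv"),
        "npv": ratio(c.tn, c.tn + c.fn, "npv"),
        "accuracy": ratio(c.tp + c.tn, c.total, "accuracy"),
        "balanced_accuracy": (sens + spec) / 2.0,
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
    }
    panel["undefined"] = undefined
    return panel


# ---------------------------------------------------------------------------
# Wilson interval


@dataclass
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.lower - 1e-12 <= self.point <= self.upper + 1e-12):
            raise ValidationError("interval must contain the point estimate")


def wilson_interval(successes: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValidationError("successes must be between 0 and n")
    lower, upper = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # boundary cases are exact for the Wilson interval; guard float error
    if successes == 0:
        lower = 0.0
    if successes == n:
        upper = 1.0
    return IntervalEstimate(point=successes / n,
                            lower=float(np.clip(lower, 0.0, 1.0)),
                            upper=float(np.clip(upper, 0.0, 1.0)),
                            level=level)


# ---------------------------------------------------------------------------
# Fisher exact test


def fisher_exact(c: ConfusionCounts) -> dict:
    """Fisher exact test on the 2x2 table [[tp, fn], [fp, tn]].

    Returns the one-sided (greater: classification better than chance) and
    two-sided p-values; the two-sided value sums all tables with fixed
    margins whose point probability does not exceed the observed one.
    """
    table = [[c.tp, c.fn], [c.fp, c.tn]]
    p_greater = float(stats.fisher_exact(table, alternative="greater").pvalue)
    p_two = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return {"p_one_sided_greater": p_greater, "p_two_sided": p_two,
            "odds_ratio": float(stats.fisher_exact(table).statistic)}


# ---------------------------------------------------------------------------
# Z comparisons


def _delong_components(scores, labels01):
    """DeLong structural components (V10, V01) and the AUC via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01).astype(int)
    x = scores[labels01 == 1]
    y = scores[labels01 == 0]
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise DataError("DeLong needs both classes")
    all_s = np.concatenate([x, y])
    r_all = stats.rankdata(all_s)          # midranks over the pooled sample
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_x) / n            # P(score_neg < score_pos | pos i)
    v01 = 1.0 - (r_all[m:] - r_y) / m
    return auc, v10, v01


def delong_variance(scores, labels01) -> tuple[float, float]:
    """AUC and its DeLong variance estimate for one ROC curve."""
    auc, v10, v01 = _delong_components(scores, labels01)
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def z_compare_auc(roc_a: RocCurve, roc_b: RocCurve) -> dict:
    """Z-statistic comparison of two independent ROC curves (DeLong
    variance estimator).  Identical curves give Z = 0, p = 1."""
    if roc_a.scores is None or roc_b.scores is None:
        raise ValidationError("ROC curves must carry score/label provenance")
    auc_a, var_a = delong_variance(roc_a.scores, roc_a.labels)
    auc_b, var_b = delong_variance(roc_b.scores, roc_b.labels)
    diff = auc_a - auc_b
    var = var_a + var_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return {"z": 0.0, "p_value": 1.0, "auc_a": auc_a, "auc_b": auc_b}
        raise DataError("degenerate DeLong variance with unequal AUCs")
    z = diff / math.sqrt(var)
    return {"z": float(z), "p_value": float(2 * stats.norm.sf(abs(z))),
            "auc_a": auc_a, "auc_b": auc_b}


def z_compare_proportions(successes_a: int, n_a: int,
                          successes_b: int | None = None,
                          n_b: int | None = None,
                          null_p: float = 0.5) -> dict:
    """Two-proportion Z (pooled variance), or one proportion against a
    fixed null (default 1:2 split, p0 = 0.5) when only one pair is given."""
    if n_a < 1:
        raise ValidationError("n_a must be >= 1")
    p_a = successes_a / n_a
    if successes_b is None:
        se = math.sqrt(null_p * (1 - null_p) / n_a)
        if se == 0:
            raise DataError("degenerate variance")
        z = (p_a - null_p) / se
    else:
        if n_b is None or n_b < 1:
            raise ValidationError("n_b must be >= 1")
        p_b = successes_b / n_b
        pool = (successes_a + successes_b) / (n_a + n_b)
        se = math.sqrt(pool * (1 - pool) * (1 / n_a + 1 / n_b))
        if se == 0:
            if p_a == p_b:
                return {"z": 0.0, "p_value": 1.0}
            raise DataError("degenerate pooled variance")
        z = (p_a - p_b) / se
    return {"z": float(z), "p_value": float(2 * stats.norm.sf(abs(z)))}
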