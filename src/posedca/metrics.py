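"""Classifier performance: confusion counts, ROC/AUC, Youden cut-points, Brier.

Conventions used throughout the package:

* the positive class is label 1 (supine preferred);
* a score is called positive when ``score >= threshold`` (closed on the
  positive side) — the same rule the net-benefit module applies;
* measures whose denominator is empty are returned as NaN ("not available"),
  never silently as 0;
* probabilities entering the Brier score are probabilities of class 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve


class MetricsError(ValueError):
    """Raised for invalid metric inputs (empty, single-class, mismatched)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies at one threshold; positive class = 1 (supine)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricsError("confusion counts must be nonnegative")
        if self.n == 0:
            raise MetricsError("confusion counts sum to zero")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class BasicMeasures:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden: float


@dataclass(frozen=True)
class RocResult:
    """ROC points, tie-corrected AUC, and a DeLong 95% CI."""

    points: np.ndarray  # columns: (1 - specificity, sensitivity)
    auc: float
    ci95: tuple[float, float]


def _validate_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise MetricsError("scores and labels must be 1-d arrays of equal length")
    if s.size == 0:
        raise MetricsError("empty input")
    if not np.all(np.isin(y, (0, 1))):
        raise MetricsError("labels must be binary")
    return s, y.astype(int)


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally a positive call for every ``score >= threshold`` against labels."""
    s, y = _validate_scores_labels(scores, labels)
    pos = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
        tn=int(np.sum(~pos & (y == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def basic_measures(c: ConfusionCounts) -> BasicMeasures:
    """Sensitivity, specificity, PPV, NPV, accuracy and the Youden index.

    Youden = sensitivity + specificity - 1, in [-1, 1]; NaN when either
    class is absent.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    return BasicMeasures(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.n),
        youden=sens + spec - 1.0,
    )


def _auc_mann_whitney(s: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected AUC: concordant pairs plus half ties over all pairs."""
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    ranks = stats.rankdata(s)  # midranks handle ties
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC via midrank structural components."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve_auc(scores, labels) -> RocResult:
    """ROC curve with tie-corrected Mann-Whitney AUC and DeLong 95% CI."""
    s, y = _validate_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise MetricsError("both classes must be present for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = _auc_mann_whitney(s, y)
    se = math.sqrt(max(_delong_variance(s, y), 0.0))
    z = stats.norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return RocResult(points=np.column_stack([fpr, tpr]), auc=auc, ci95=(lo, hi))


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    counts: ConfusionCounts
    measures: BasicMeasures


def youden_optimal_cutpoint(scores, labels) -> CutpointResult:
    """Threshold maximizing the Youden index, scanned exhaustively.

    Candidates are the midpoints between adjacent distinct scores plus
    sentinels at +/- infinity (call-everyone / call-no-one).  Ties on the
    Youden index are broken toward the higher-specificity (higher) cut.
    """
    s, y = _validate_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise MetricsError("both classes must be present to choose a cut-point")
    u = np.unique(s)
    candidates = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    best = None
    for t in candidates:
        c = confusion_at_threshold(s, y, t)
        m = basic_measures(c)
        key = (m.youden, m.specificity, t)
        if best is None or key > best[0]:
            best = (key, CutpointResult(float(t), c, m))
    return best[1]


def brier_score(probs, outcomes, weights=None) -> float:
    """(Weighted) mean squared distance between probabilities and outcomes.

    Unweighted: mean of (p_i - o_i)^2.  Weighted: sum w_i (p_i - o_i)^2
    divided by sum w_i, which reduces to the unweighted score under equal
    weights.  Lower is better; 0 is a perfect forecast.
    """
    p = np.asarray(probs, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise MetricsError("probs and outcomes must be 1-d arrays of equal length")
    if np.any(p < 0) or np.any(p > 1):
        raise MetricsError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(o, (0.0, 1.0))):
        raise MetricsError("outcomes must be binary")
    sq = (p - o) ** 2
    if weights is None:
        return float(np.mean(sq))
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise MetricsError("weights must match probs in length")
    if np.any(w < 0):
        raise MetricsError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise MetricsError("weights must not all be zero")
    return float(np.sum(w * sq) / total)
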