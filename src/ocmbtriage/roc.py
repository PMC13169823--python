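"""ROC curves, Mann–Whitney AUCs with DeLong inference, cutoff selection.

The AUC is estimated by the Mann–Whitney statistic (ties count 1/2) and its
variance by DeLong's structural-components estimator, which also yields the
paired z-test for two correlated AUCs measured on the same subjects.
Confidence intervals are normal-approximation on the plain AUC scale, clipped
to [0, 1] (the logit-scale variant common in some tools is deliberately not
used; this matches the default of the usual ROC tooling).

Thresholding is inclusive throughout: a score >= threshold predicts positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._exceptions import (
    InsufficientDataError,
    InvalidValueError,
    NoFeasibleCutoffError,
    UndefinedCorrelationError,
)

__all__ = [
    "RocCurve",
    "AucEstimate",
    "DelongComparison",
    "SpearmanResult",
    "empirical_auc",
    "roc_curve",
    "delong_ci",
    "delong_paired_test",
    "select_cutoff",
    "operating_point",
    "rank_correlation",
]


@dataclass(frozen=True)
class RocCurve:
    """Operating points at every observed score, inclusive convention.

    ``thresholds`` is descending with a leading +inf sentinel (the
    flag-nobody rule), so the first point is (sens 0, spec 1) and the last
    (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def auc(self) -> float:
        """Trapezoidal area under the (1 - specificity, sensitivity) curve."""
        return float(np.trapezoid(self.sensitivity, 1.0 - self.specificity))

    def plot(self, ax=None, label: Optional[str] = None):
        """Draw the curve on a matplotlib axes (created if omitted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1.0 - self.specificity, self.sensitivity, label=label, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        if label:
            ax.legend(loc="lower right")
        return ax


@dataclass(frozen=True)
class AucEstimate:
    """Mann–Whitney AUC with DeLong standard error and normal CI."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    degenerate: bool = False  # all scores tied; se is 0 by construction


class DelongComparison(NamedTuple):
    statistic: float
    pvalue: float
    auc_a: float
    auc_b: float


class SpearmanResult(NamedTuple):
    correlation: float
    pvalue: float


def _as_score_array(scores, name: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidValueError(f"{name} contains non-finite scores")
    return arr


def empirical_auc(pos_scores, neg_scores) -> float:
    """Mann–Whitney AUC: P(pos > neg) + 0.5 P(pos == neg) over all pairs.

    Computed from midranks in O((m+n) log(m+n)); identical to the explicit
    pairwise count.
    """
    pos = _as_score_array(pos_scores, "pos_scores")
    neg = _as_score_array(neg_scores, "neg_scores")
    m, n = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def roc_curve(scores, labels) -> RocCurve:
    """All operating points of the rule score >= threshold.

    The trapezoidal area of the result equals :func:`empirical_auc` of the
    same data to round-off.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if s.shape != y.shape:
        raise InvalidValueError("scores and labels differ in length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise InsufficientDataError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr)


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    # psi(x, y) = 1 if x > y, 1/2 if tied, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 (per positive), V01 (per negative)


def delong_ci(pos_scores, neg_scores, level: float = 0.95) -> AucEstimate:
    """AUC with DeLong structural-components variance and normal CI.

    With every score tied the variance estimator is exactly zero; the result
    is returned with ``degenerate=True`` rather than raising.
    """
    if not 0 < level < 1:
        raise InvalidValueError(f"level must be in (0, 1), got {level}")
    pos = _as_score_array(pos_scores, "pos_scores")
    neg = _as_score_array(neg_scores, "neg_scores")
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError("need at least 2 scores per class for a DeLong CI")
    v10, v01 = _delong_components(pos, neg)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return AucEstimate(
        auc=auc,
        se=se,
        ci_low=float(np.clip(auc - z * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + z * se, 0.0, 1.0)),
        level=level,
        degenerate=bool(se == 0.0),
    )


def delong_paired_test(scores_a, scores_b, labels) -> DelongComparison:
    """Paired DeLong z-test for two correlated AUCs on the same subjects."""
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if not (a.shape == b.shape == y.shape):
        raise InvalidValueError("scores_a, scores_b and labels must have equal length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise InsufficientDataError("both classes must be present")
    pos_mask = y == 1
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((a, b)):
        v10[k], v01[k] = _delong_components(s[pos_mask], s[~pos_mask])
        aucs[k] = v10[k].mean()
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        stat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        pval = 1.0 if diff == 0 else 0.0
    else:
        stat = diff / math.sqrt(var_diff)
        pval = float(2 * stats.norm.sf(abs(stat)))
    return DelongComparison(statistic=stat, pvalue=pval, auc_a=float(aucs[0]), auc_b=float(aucs[1]))


def operating_point(curve: RocCurve, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score >= ``threshold`` on the curve."""
    finite = np.isfinite(curve.thresholds)
    qualifying = np.where(finite & (curve.thresholds >= threshold))[0]
    if qualifying.size == 0:
        return 0.0, 1.0  # flags nobody
    idx = qualifying[-1]  # thresholds descend: last match is the tightest score >= t
    return float(curve.sensitivity[idx]), float(curve.specificity[idx])


def _snap_up(value: float, grid: float) -> float:
    steps = value / grid
    # value already on the grid (to round-off) stays put
    nearest = round(steps)
    if math.isclose(steps, nearest, rel_tol=0, abs_tol=1e-9):
        return nearest * grid
    return math.ceil(steps) * grid


def select_cutoff(
    curve: RocCurve, min_specificity: float, snap_grid: Optional[float] = None
) -> float:
    """Highest-sensitivity threshold with specificity strictly above the floor.

    Among finite operating points with specificity > ``min_specificity`` the
    threshold of maximal sensitivity is chosen; ties break toward higher
    specificity, then toward the higher threshold.  With ``snap_grid`` the
    chosen threshold is rounded up to the next grid multiple (which can only
    tighten the rule, so the constraint is preserved; it is re-verified
    regardless).
    """
    if snap_grid is not None and snap_grid <= 0:
        raise InvalidValueError("snap_grid must be positive")
    finite = np.isfinite(curve.thresholds)
    ok = finite & (curve.specificity > min_specificity)
    if not np.any(ok):
        raise NoFeasibleCutoffError(
            f"no operating point has specificity > {min_specificity}"
        )
    idx = np.where(ok)[0]
    order = sorted(
        idx,
        key=lambda i: (
            curve.sensitivity[i],
            curve.specificity[i],
            curve.thresholds[i],
        ),
        reverse=True,
    )
    best = float(curve.thresholds[order[0]])
    if snap_grid is not None:
        best = _snap_up(best, snap_grid)
        _, spec = operating_point(curve, best)
        if not spec > min_specificity:  # pragma: no cover - snapping only tightens
            raise NoFeasibleCutoffError(
                f"snapped cutoff {best} violates specificity > {min_specificity}"
            )
    return best


def rank_correlation(x, y) -> SpearmanResult:
    """Spearman rank correlation (midranks for ties) with two-sided p-value."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise InvalidValueError("x and y must have equal length")
    if xa.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise UndefinedCorrelationError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(xa, ya)
    return SpearmanResult(correlation=float(res.statistic), pvalue=float(res.pvalue))
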