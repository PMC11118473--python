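"""Regression and classification metrics under the low-score-pathogenic convention.

All classification metrics in this package treat a *smaller* predicted %WT
activity as *more pathogenic*: a variant is called positive at threshold t
when its predicted activity is <= t.  This is the opposite of the usual
"high score = positive" convention, so ROC construction is written out here
rather than delegated to a generic library.

Metric definitions
------------------
* ``pearson`` — product-moment correlation between measured and predicted
  activity.
* ``r_squared`` — 1 - SS_res/SS_tot; unlike the squared correlation this can
  be negative, and it is the only metric here that is sensitive to the scale
  of the predictions (hence the normalization stage).
* ``kendall_tau`` — the plain pairwise sign statistic
  ``sum sign((y_i-y_j)(yhat_i-yhat_j)) / (n(n-1)/2)``: tied pairs contribute
  0 to the numerator but stay in the denominator (tau-a).  Note that library
  defaults usually compute tau-b, which rescales for ties.
* ``auc`` — probability that a random pathogenic variant is predicted below
  a random benign one, with a half credit for ties.  Computed both by pair
  counting and as the trapezoidal area under the tie-aware ROC curve; the two
  must agree to machine precision.
* ``truncated_auc`` — area under the ROC restricted to FPR in [0, 0.2]
  (linear interpolation at the boundary), divided by 0.2 so a perfect
  classifier scores 1.  Emphasizes the clinically relevant low-FPR regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError

#: Metrics used for ranking (all larger-is-better after normalization).
RANKING_METRICS = ("pearson", "kendall_tau", "auc", "truncated_auc")
#: All reported metrics (r_squared is reported but never ranked: it demands a
#: calibrated predictor, which is a stricter requirement than ordering).
ALL_METRICS = RANKING_METRICS + ("r_squared",)

DEFAULT_MAX_FPR = 0.2


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    n: int


@dataclass(frozen=True)
class RocCurve:
    """Tie-aware ROC polyline under the <=t calling convention.

    Vertices are anchored at (0, 0) and (1, 1); thresholds are the sorted
    distinct prediction values (the anchor carries -inf).  A group of tied
    scores containing both classes contributes a single diagonal segment.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pathogenic: int
    n_benign: int

    def __len__(self) -> int:
        return len(self.fpr)


def _validate_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise UndefinedMetricError("inputs must be 1-d arrays of equal length")
    if len(y) < 2:
        raise UndefinedMetricError("need at least two observations")
    if np.isnan(y).any() or np.isnan(yhat).any():
        raise UndefinedMetricError("inputs contain missing values")
    return y, yhat


def _validate_classes(yhat, z) -> tuple[np.ndarray, np.ndarray]:
    yhat = np.asarray(yhat, dtype=float)
    z = np.asarray(z)
    if yhat.shape != z.shape or yhat.ndim != 1:
        raise UndefinedMetricError("inputs must be 1-d arrays of equal length")
    if np.isnan(yhat).any():
        raise UndefinedMetricError("predictions contain missing values")
    z = z.astype(float)
    if not np.isin(z, (0.0, 1.0)).all():
        raise UndefinedMetricError("labels must be 0/1")
    if z.min() == z.max():
        raise UndefinedMetricError("both classes must be present")
    return yhat, z.astype(int)


# ---------------------------------------------------------------------------
# regression metrics


def _pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    dy = y - y.mean()
    dh = yhat - yhat.mean()
    ssy = float(dy @ dy)
    ssh = float(dh @ dh)
    if ssy == 0.0 or ssh == 0.0:
        raise UndefinedMetricError("zero variance input to Pearson correlation")
    return float(dy @ dh) / np.sqrt(ssy * ssh)


def pearson(y, yhat) -> MetricValue:
    y, yhat = _validate_pair(y, yhat)
    return MetricValue("pearson", _pearson(y, yhat), len(y))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("constant measured values: R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared(y, yhat) -> MetricValue:
    y, yhat = _validate_pair(y, yhat)
    return MetricValue("r_squared", _r_squared(y, yhat), len(y))


def _kendall_tau(y: np.ndarray, yhat: np.ndarray) -> float:
    # vectorized O(n^2) sign-sum; n is a few hundred at most
    sy = np.sign(y[:, None] - y[None, :])
    sh = np.sign(yhat[:, None] - yhat[None, :])
    n = len(y)
    num = float(np.sum(np.triu(sy * sh, k=1)))
    return num / (n * (n - 1) / 2.0)


def kendall_tau(y, yhat) -> MetricValue:
    y, yhat = _validate_pair(y, yhat)
    return MetricValue("kendall_tau", _kendall_tau(y, yhat), len(y))


# ---------------------------------------------------------------------------
# classification metrics


def roc_curve(yhat, z) -> RocCurve:
    """Tie-aware ROC: TPR(t) and FPR(t) at every distinct prediction value t.

    TPR(t) = fraction of pathogenic variants with prediction <= t, FPR(t)
    likewise over benign variants; (0, 0) is prepended.
    """
    yhat, z = _validate_classes(yhat, z)
    n1 = int(z.sum())
    n0 = len(z) - n1
    order = np.argsort(yhat, kind="mergesort")
    ys, zs = yhat[order], z[order]
    # last index of each tied group = vertex per distinct threshold
    last = np.flatnonzero(np.r_[ys[1:] != ys[:-1], True])
    tp = np.cumsum(zs)[last]
    fp = np.cumsum(1 - zs)[last]
    fpr = np.concatenate(([0.0], fp / n0))
    tpr = np.concatenate(([0.0], tp / n1))
    thresholds = np.concatenate(([-np.inf], ys[last]))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, n_pathogenic=n1, n_benign=n0)


def _auc_pairs(yhat: np.ndarray, z: np.ndarray) -> float:
    """Pair statistic: P(yhat_path < yhat_benign) + 0.5 P(equal)."""
    path = yhat[z == 1]
    benign_sorted = np.sort(yhat[z == 0])
    n0 = len(benign_sorted)
    right = np.searchsorted(benign_sorted, path, side="right")
    left = np.searchsorted(benign_sorted, path, side="left")
    greater = (n0 - right).sum()  # benign strictly above each pathogenic score
    ties = (right - left).sum()
    return float(greater + 0.5 * ties) / (len(path) * n0)


def _trapezoid(curve: RocCurve) -> float:
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc(yhat, z) -> MetricValue:
    """AUC by pair counting, cross-checked against the ROC trapezoid area."""
    yhat, z = _validate_classes(yhat, z)
    by_pairs = _auc_pairs(yhat, z)
    by_area = _trapezoid(roc_curve(yhat, z))
    if abs(by_pairs - by_area) > 1e-10:
        raise AssertionError(
            f"internal inconsistency: pair AUC {by_pairs} != trapezoid AUC {by_area}"
        )
    return MetricValue("auc", by_pairs, len(z))


def _truncated_area(curve: RocCurve, max_fpr: float) -> float:
    fpr, tpr = curve.fpr, curve.tpr
    if fpr[-1] <= max_fpr:
        return float(np.trapezoid(tpr, fpr))
    cut = int(np.searchsorted(fpr, max_fpr, side="right"))  # first vertex beyond
    xs = fpr[:cut]
    ys = tpr[:cut]
    # linearly interpolate TPR at the truncation boundary
    x0, y0 = fpr[cut - 1], tpr[cut - 1]
    x1, y1 = fpr[cut], tpr[cut]
    y_b = y0 if x1 == x0 else y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0)
    xs = np.concatenate((xs, [max_fpr]))
    ys = np.concatenate((ys, [y_b]))
    return float(np.trapezoid(ys, xs))


def truncated_auc_from_curve(curve: RocCurve, max_fpr: float = DEFAULT_MAX_FPR) -> MetricValue:
    value = _truncated_area(curve, max_fpr) / max_fpr
    return MetricValue("truncated_auc", value, curve.n_pathogenic + curve.n_benign)


def truncated_auc(yhat, z, max_fpr: float = DEFAULT_MAX_FPR) -> MetricValue:
    return truncated_auc_from_curve(roc_curve(yhat, z), max_fpr)


def _tauc(yhat: np.ndarray, z: np.ndarray, max_fpr: float = DEFAULT_MAX_FPR) -> float:
    return _truncated_area(roc_curve(yhat, z), max_fpr) / max_fpr


# fast float-returning dispatch used by the bootstrap stage
_POINT_FUNCS = {
    "pearson": lambda y, yhat, z: _pearson(y, yhat),
    "r_squared": lambda y, yhat, z: _r_squared(y, yhat),
    "kendall_tau": lambda y, yhat, z: _kendall_tau(y, yhat),
    "auc": lambda y, yhat, z: _auc_pairs(*_validate_classes(yhat, z)),
    "truncated_auc": lambda y, yhat, z: _tauc(*_validate_classes(yhat, z)),
}


def compute_metric(name: str, y, yhat, z) -> float:
    """Evaluate one named metric; raises UndefinedMetricError when degenerate."""
    try:
        func = _POINT_FUNCS[name]
    except KeyError as exc:
        raise UndefinedMetricError(f"unknown metric {name!r}") from exc
    return float(func(np.asarray(y, float), np.asarray(yhat, float), z))
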