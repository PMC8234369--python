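"""Performance metrics for probabilistic binary prediction.

Accuracy (Brier score), discrimination (AUC), calibration (recalibration
intercept and slope, smoothed calibration curve, E_max, integrated
calibration index), and model-comparison reclassification measures
(continuous NRI, IDI).

Conventions: predicted probabilities are clipped to [1e-10, 1 - 1e-10]
before any logit transform; the calibration intercept follows the
calibration-in-the-large convention (logit of the prediction entered as a
fixed offset); the calibration curve is a locally weighted linear smooth
(tricube weights) of the outcome on the prediction, evaluated at the
observed predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "PredictionVector",
    "CalibrationCurve",
    "prediction_vector",
    "brier_score",
    "auc",
    "calibration_intercept_slope",
    "calibration_curve",
    "emax_ici",
    "nri_continuous",
    "idi",
]

_CLIP = 1e-10


class PredictionVector(NamedTuple):
    """Paired predicted probabilities and observed 0/1 outcomes."""

    p: np.ndarray
    y: np.ndarray


def prediction_vector(p, y) -> PredictionVector:
    """Validate and pair predictions with outcomes."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.ndim != 1 or y.ndim != 1 or len(p) != len(y):
        raise ValidationError("p and y must be one-dimensional and of equal length")
    if len(p) < 2:
        raise ValidationError("at least two observations are required")
    if np.isnan(p).any() or np.isnan(y).any():
        raise ValidationError("p and y must not contain missing values")
    if ((p <= 0) | (p >= 1)).any():
        raise ValidationError("predicted probabilities must lie strictly in (0, 1)")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("outcomes must be coded 0/1")
    return PredictionVector(p=p, y=y)


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateDataError("both outcome classes are required")


def brier_score(p, y) -> float:
    """Mean squared difference between prediction and outcome, in [0, 1]."""
    p, y = prediction_vector(p, y)
    return float(np.mean((p - y) ** 2))


def auc(p, y) -> float:
    """Area under the ROC curve (pairwise concordance, ties counted 1/2).

    Computed from mid-ranks, which is algebraically identical to the
    exhaustive count over all event/non-event pairs.
    """
    p, y = prediction_vector(p, y)
    _require_both_classes(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_intercept_slope(p, y) -> tuple[float, float]:
    """Logistic recalibration intercept and slope of the predictions.

    The slope is the MLE coefficient of logit(p) in a logistic regression
    of y on logit(p); the intercept is the MLE of an intercept-only
    logistic regression with logit(p) as a fixed offset
    (calibration-in-the-large).  A slope of 1 and intercept of 0 indicate
    perfect weak calibration.
    """
    p, y = prediction_vector(p, y)
    _require_both_classes(y)
    lp = logit(np.clip(p, _CLIP, 1.0 - _CLIP))
    if np.ptp(lp) < 1e-12:
        raise DegenerateDataError("predictions are constant; calibration slope undefined")
    res_slope = sm.GLM(
        y, np.column_stack([np.ones(len(y)), lp]), family=sm.families.Binomial()
    ).fit(maxiter=200, tol=1e-10)
    res_int = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit(maxiter=200, tol=1e-10)
    return float(res_int.params[0]), float(res_slope.params[1])


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed observed-versus-predicted calibration relationship.

    ``points`` are the sorted unique predicted probabilities; ``smoothed``
    the locally weighted estimate of the observed event probability at
    each, clipped to [0, 1].  ``deciles`` is the grouped summary used for
    the triangles of a calibration plot (mean prediction and observed
    frequency per risk-decile group).
    """

    points: np.ndarray
    smoothed: np.ndarray
    span: float
    deciles: pd.DataFrame
    n_obs: int

    def evaluate(self, p: np.ndarray) -> np.ndarray:
        """Smoothed value at each requested prediction (must be observed)."""
        p = np.asarray(p, dtype=float)
        idx = np.searchsorted(self.points, p)
        bad = (idx >= len(self.points)) | ~np.isclose(
            self.points[np.minimum(idx, len(self.points) - 1)], p, rtol=0, atol=1e-12
        )
        if bad.any():
            raise ValidationError(
                "curve and predictions are mismatched: some predictions were "
                "not among the curve's evaluation points"
            )
        return self.smoothed[idx]


def calibration_curve(p, y, span: float = 0.75, delta: float | None = None) -> CalibrationCurve:
    """Locally weighted linear calibration smooth plus a decile summary.

    ``span`` is the fraction of observations in each local neighborhood.
    ``delta`` (spacing below which points share a local fit) defaults to
    1% of the prediction range when n > 5000, which makes the smoother
    effectively linear-time on large cohorts; pass 0 to force exact local
    fits everywhere.
    """
    p, y = prediction_vector(p, y)
    n = len(p)
    if n < 20:
        raise DegenerateDataError(
            "at least 20 observations are needed for smoothing; "
            "use the decile summary alone for smaller cohorts"
        )
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must lie in (0, 1]")
    if delta is None:
        delta = 0.01 * np.ptp(p) if n > 5000 else 0.0

    points = np.unique(p)
    if len(points) == 1:
        smoothed = np.array([y.mean()])
    else:
        fitted = lowess(y, p, frac=span, it=0, delta=delta, return_sorted=True)
        xs, ys = fitted[:, 0], fitted[:, 1]
        points, first = np.unique(xs, return_index=True)
        smoothed = np.clip(ys[first], 0.0, 1.0)

    groups = pd.qcut(pd.Series(p), q=10, labels=False, duplicates="drop")
    dec = (
        pd.DataFrame({"group": groups, "p": p, "y": y})
        .groupby("group", observed=True)
        .agg(mean_predicted=("p", "mean"), observed_frequency=("y", "mean"), n=("y", "size"))
        .reset_index(drop=True)
    )
    return CalibrationCurve(points=points, smoothed=smoothed, span=span, deciles=dec, n_obs=n)


def emax_ici(curve: CalibrationCurve, p, y) -> tuple[float, float]:
    """Maximum (E_max) and mean (ICI) absolute calibration error.

    Both compare each predicted probability with the smoothed observed
    probability at that prediction: E_max is the worst-case discrepancy
    over the observed prediction range, the integrated calibration index
    is the subject-averaged discrepancy; hence ICI <= E_max always.
    """
    p, y = prediction_vector(p, y)
    if curve.n_obs != len(p):
        raise ValidationError("curve was computed from a different prediction vector")
    smooth_at_p = curve.evaluate(p)
    abs_err = np.abs(p - smooth_at_p)
    e_max = float(np.max(np.abs(curve.points - curve.smoothed)))
    ici = float(np.mean(abs_err))
    return e_max, ici


def _check_pair(p_new, p_old, y):
    p_new = np.asarray(p_new, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(p_new) == len(p_old) == len(y)):
        raise ValidationError("p_new, p_old and y must have equal length")
    _require_both_classes(y)
    return p_new, p_old, y


def nri_continuous(p_new, p_old, y) -> tuple[float, float, float]:
    """Continuous (threshold-free) net reclassification improvement.

    Events should move up, non-events down: the event component is the net
    proportion of events whose predicted risk increased, the non-event
    component the net proportion of non-events whose risk decreased, and
    the total their sum (range -2 to 2).  Ties count in neither direction.
    """
    p_new, p_old, y = _check_pair(p_new, p_old, y)
    up = p_new > p_old
    down = p_new < p_old
    ev = y == 1
    ne = ~ev
    event_nri = float(up[ev].mean() - down[ev].mean())
    nonevent_nri = float(down[ne].mean() - up[ne].mean())
    return event_nri, nonevent_nri, event_nri + nonevent_nri


def idi(p_new, p_old, y) -> float:
    """Integrated discrimination improvement.

    Change, from old to new model, in the discrimination slope — the
    difference between the mean predicted risk of events and of
    non-events.
    """
    p_new, p_old, y = _check_pair(p_new, p_old, y)
    ev = y == 1
    ne = ~ev
    slope_new = p_new[ev].mean() - p_new[ne].mean()
    slope_old = p_old[ev].mean() - p_old[ne].mean()
    return float(slope_new - slope_old)
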