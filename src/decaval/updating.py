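"""Model updating by closed testing, and extended-predictor refits.

When a published logistic prediction model is carried to a new cohort, it
can be left untouched, recalibrated (intercept only, or intercept plus a
common slope on its linear predictor), or fully revised.  The closed
testing procedure chooses among these by likelihood-ratio tests of each
simpler variant against the full revision, selecting the most parsimonious
variant that the data do not reject — so the published coefficients are
retained unless there is real evidence of miscalibration.

Two extended refits are also provided: a "continuous" model that swaps the
ordinal age band and vegetative-status indicator for age in years and the
CRS-r consciousness score, and a "complete" model that further adds ICU
length of stay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

from .errors import DegenerateDataError, SeparationError
from .model import (
    SCORE_PREDICTORS,
    CoefficientSet,
    _predictor_frame,
    linear_predictor,
    predict_probability,
)
from .simulate import CohortTable

__all__ = [
    "UPDATE_VARIANTS",
    "EXTENDED_VARIANTS",
    "FittedModel",
    "LRTestResult",
    "ClosedTestOutcome",
    "fit_update_model",
    "fit_extended_model",
    "lr_test",
    "closed_test_select",
]

UPDATE_VARIANTS = (
    "original",
    "calibration_in_the_large",
    "logistic_calibration",
    "revision",
)
EXTENDED_VARIANTS = ("continuous", "complete")

CONTINUOUS_PREDICTORS = (
    "age_years",
    "crs_r",
    "saliva_score",
    "cough_score",
    "pathogenesis_score",
)
COMPLETE_PREDICTORS = CONTINUOUS_PREDICTORS + ("icu_los_days",)

_N_FREE = {
    "original": 0,
    "calibration_in_the_large": 1,
    "logistic_calibration": 2,
    "revision": 6,
    "continuous": 6,
    "complete": 7,
}

# nesting chains used to validate likelihood-ratio comparisons
_NESTING_RANK = {
    "original": ("update", 0),
    "calibration_in_the_large": ("update", 1),
    "logistic_calibration": ("update", 2),
    "revision": ("update", 3),
    "continuous": ("extended", 0),
    "complete": ("extended", 1),
}

# |linear predictor| beyond this means fitted probabilities within ~1e-13 of
# 0/1 — treated as (quasi-)complete separation
_SEPARATION_LP = 30.0


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or fixed) logistic model variant.

    ``coefficients`` always lives on the predictor space, so prediction is
    uniform across variants: for the recalibration variants the one or two
    free parameters are folded into the original coefficients (an updated
    intercept, or a common factor on all slopes), and the raw free
    parameters are kept in ``free_params`` for reporting.
    """

    variant: str
    coefficients: CoefficientSet
    n_free_params: int
    log_likelihood: float
    n_obs: int
    free_params: Mapping[str, float] = field(default_factory=dict)
    used_ridge: bool = False
    standard_errors: Mapping[str, float] = field(default_factory=dict)

    def predict(self, cohort) -> np.ndarray:
        return predict_probability(_as_frame(cohort), self.coefficients)


@dataclass(frozen=True)
class LRTestResult:
    comparison: str
    df: int
    statistic: float
    p_value: float


@dataclass(frozen=True)
class ClosedTestOutcome:
    """Result of the closed testing procedure.

    ``selected`` is the most parsimonious update variant whose test against
    the full revision is non-significant at ``alpha``; the revision itself
    is selected only when all three tests reject.
    """

    selected: str
    tests: tuple[LRTestResult, ...]
    alpha: float
    models: Mapping[str, FittedModel]


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return cohort.data
    return cohort


def _check_outcome(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateDataError(
            "cohort outcome has a single class; logistic fitting is undefined"
        )


def _logistic_mle(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    ridge: bool = False,
    ridge_lambda: float = 1e-6,
    penalize: np.ndarray | None = None,
):
    """Binomial MLE via IRLS; optional weak ridge fallback on the slopes.

    Returns (params, log_likelihood, standard_errors).  Raises
    :class:`SeparationError` when the unpenalized fit diverges and the
    ridge fallback was not requested.
    """
    off = np.zeros(len(y)) if offset is None else offset
    if not ridge:
        glm = sm.GLM(y, X, family=sm.families.Binomial(), offset=off)
        try:
            with warnings.catch_warnings():
                # separation is detected and raised as SeparationError below
                warnings.simplefilter("ignore")
                res = glm.fit(maxiter=200, tol=1e-10)
        except Exception as err:  # perfect-separation errors vary by version
            raise SeparationError(
                f"logistic fit failed ({err}); refit with ridge=True"
            ) from err
        lp = X @ res.params + off
        if (not res.converged) or np.abs(lp).max() > _SEPARATION_LP:
            raise SeparationError(
                "logistic fit diverged (complete or quasi-complete separation "
                "suspected); refit with ridge=True"
            )
        return np.asarray(res.params), float(res.llf), np.asarray(res.bse)

    # weakly penalized Newton iterations: -ll + lambda/2 * ||slopes||^2
    p = X.shape[1]
    mask = np.ones(p) if penalize is None else np.asarray(penalize, dtype=float)
    beta = np.zeros(p)
    for _ in range(200):
        lp = X @ beta + off
        mu = expit(lp)
        grad = X.T @ (mu - y) + ridge_lambda * mask * beta
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * W[:, None]).T @ X + ridge_lambda * np.diag(mask)
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.abs(grad).max() < 1e-8:
            break
    lp = X @ beta + off
    ll = float(np.sum(y * lp - np.logaddexp(0.0, lp)))
    W = np.clip(expit(lp) * (1.0 - expit(lp)), 1e-12, None)
    H = (X * W[:, None]).T @ X + ridge_lambda * np.diag(mask)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, ll, se


def _fixed_loglik(y: np.ndarray, lp: np.ndarray) -> float:
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def fit_update_model(
    cohort,
    original: CoefficientSet,
    variant: str,
    ridge: bool = False,
    slope_on_full_lp: bool = True,
) -> FittedModel:
    """Fit one of the four update variants of the closed testing family.

    - ``original``: no free parameters; the log-likelihood is evaluated at
      the supplied coefficients.
    - ``calibration_in_the_large``: the original linear predictor enters as
      a fixed offset and only a new intercept shift is estimated.
    - ``logistic_calibration``: a new intercept and a single slope on the
      original linear predictor (by default including its intercept; set
      ``slope_on_full_lp=False`` to rescale the intercept-free part).
    - ``revision``: full re-estimation of intercept plus the five
      component-score coefficients.
    """
    if variant not in UPDATE_VARIANTS:
        raise ValueError(f"unknown update variant {variant!r}")
    df = _as_frame(cohort)
    y = df["decannulated"].to_numpy(dtype=float)
    _check_outcome(y)
    n = len(df)
    lp_orig = np.asarray(linear_predictor(df, original), dtype=float)

    if variant == "original":
        return FittedModel(
            variant=variant,
            coefficients=original,
            n_free_params=0,
            log_likelihood=_fixed_loglik(y, lp_orig),
            n_obs=n,
        )

    if variant == "calibration_in_the_large":
        X = np.ones((n, 1))
        params, ll, se = _logistic_mle(
            y, X, offset=lp_orig, ridge=ridge, penalize=np.zeros(1)
        )
        delta = float(params[0])
        coefs = CoefficientSet(
            intercept=original.intercept + delta,
            coefficients=dict(original.coefficients),
            provenance="refit",
            encoding=original.encoding,
        )
        return FittedModel(
            variant=variant,
            coefficients=coefs,
            n_free_params=1,
            log_likelihood=ll,
            n_obs=n,
            free_params={"delta_intercept": delta},
            used_ridge=ridge,
            standard_errors={"delta_intercept": float(se[0])},
        )

    if variant == "logistic_calibration":
        lp_used = lp_orig if slope_on_full_lp else lp_orig - original.intercept
        if np.ptp(lp_used) < 1e-12:
            raise DegenerateDataError(
                "original linear predictor is constant; calibration slope undefined"
            )
        X = np.column_stack([np.ones(n), lp_used])
        params, ll, se = _logistic_mle(y, X, ridge=ridge, penalize=np.array([0.0, 1.0]))
        a, b = float(params[0]), float(params[1])
        new_intercept = a + (b * original.intercept if slope_on_full_lp else 0.0)
        coefs = CoefficientSet(
            intercept=new_intercept,
            coefficients={k: b * v for k, v in original.coefficients.items()},
            provenance="refit",
            encoding=original.encoding,
        )
        return FittedModel(
            variant=variant,
            coefficients=coefs,
            n_free_params=2,
            log_likelihood=ll,
            n_obs=n,
            free_params={"intercept": a, "slope": b},
            used_ridge=ridge,
            standard_errors={"intercept": float(se[0]), "slope": float(se[1])},
        )

    # revision: intercept + the five component scores
    names = SCORE_PREDICTORS
    Xf = _predictor_frame(df, names, original.encoding).to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), Xf])
    penalize = np.r_[0.0, np.ones(len(names))]
    params, ll, se = _logistic_mle(y, X, ridge=ridge, penalize=penalize)
    coefs = CoefficientSet(
        intercept=float(params[0]),
        coefficients={nm: float(v) for nm, v in zip(names, params[1:])},
        provenance="refit",
        encoding=original.encoding,
    )
    ses = {"intercept": float(se[0])}
    ses.update({nm: float(v) for nm, v in zip(names, se[1:])})
    return FittedModel(
        variant="revision",
        coefficients=coefs,
        n_free_params=6,
        log_likelihood=ll,
        n_obs=n,
        free_params={"intercept": float(params[0]), **coefs.coefficients},
        used_ridge=ridge,
        standard_errors=ses,
    )


def fit_extended_model(cohort, variant: str, ridge: bool = False) -> FittedModel:
    """Fit the continuous (age in years + CRS-r) or complete (+ ICU days)
    extended logistic model.

    Continuous predictors are standardized internally for numerical
    stability; reported coefficients are on the original scales.
    """
    if variant not in EXTENDED_VARIANTS:
        raise ValueError(f"unknown extended variant {variant!r}")
    names = CONTINUOUS_PREDICTORS if variant == "continuous" else COMPLETE_PREDICTORS
    df = _as_frame(cohort)
    y = df["decannulated"].to_numpy(dtype=float)
    _check_outcome(y)
    n = len(df)
    Xf = _predictor_frame(df, names, CoefficientSet(0.0, {}).encoding)
    X = Xf.to_numpy(dtype=float)

    scale_cols = [i for i, nm in enumerate(names) if nm in ("age_years", "crs_r", "icu_los_days")]
    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for i in scale_cols:
        center[i] = X[:, i].mean()
        s = X[:, i].std(ddof=0)
        scale[i] = s if s > 0 else 1.0
    Xs = (X - center) / scale
    Xd = np.column_stack([np.ones(n), Xs])
    penalize = np.r_[0.0, np.ones(len(names))]
    params, ll, se = _logistic_mle(y, Xd, ridge=ridge, penalize=penalize)

    slopes = params[1:] / scale
    intercept = float(params[0] - np.sum(params[1:] * center / scale))
    se_slopes = se[1:] / scale
    coefs = CoefficientSet(
        intercept=intercept,
        coefficients={nm: float(b) for nm, b in zip(names, slopes)},
        provenance="refit",
    )
    return FittedModel(
        variant=variant,
        coefficients=coefs,
        n_free_params=len(names) + 1,
        log_likelihood=ll,
        n_obs=n,
        free_params={"intercept": intercept, **coefs.coefficients},
        used_ridge=ridge,
        standard_errors={nm: float(s) for nm, s in zip(names, se_slopes)},
    )


def lr_test(full: FittedModel, reduced: FittedModel) -> LRTestResult:
    """Likelihood-ratio test of a nested (reduced) variant against a fuller one.

    The statistic is ``2 (ll_full - ll_reduced)`` (clipped at zero, since
    both are maxima over nested spaces), with degrees of freedom equal to
    the difference in free-parameter counts and a chi-square upper-tail
    p-value.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted on different numbers of observations")
    fam_f, rank_f = _NESTING_RANK[full.variant]
    fam_r, rank_r = _NESTING_RANK[reduced.variant]
    if fam_f != fam_r or rank_f <= rank_r:
        raise ValueError(
            f"{reduced.variant!r} is not nested strictly inside {full.variant!r}"
        )
    if full.n_free_params <= reduced.n_free_params:
        raise ValueError("full model must have more free parameters than reduced")
    raw = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if raw < -1e-6:
        raise RuntimeError(
            f"likelihood ordering violated ({raw:.3g} < 0); optimizer failure"
        )
    stat = max(raw, 0.0)
    df = full.n_free_params - reduced.n_free_params
    return LRTestResult(
        comparison=f"{full.variant} vs. {reduced.variant}",
        df=df,
        statistic=stat,
        p_value=float(chi2.sf(stat, df)),
    )


def closed_test_select(
    cohort,
    original: CoefficientSet,
    alpha: float = 0.05,
    ridge: bool = False,
    slope_on_full_lp: bool = True,
) -> ClosedTestOutcome:
    """Run the closed testing procedure and select an update variant.

    All four variants are fitted; the revision is tested against the
    original, the intercept-only recalibration, and the intercept+slope
    recalibration in that (parsimony) order, and the first variant not
    rejected at ``alpha`` is selected.  If every test rejects, the full
    revision is adopted.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    models = {
        v: fit_update_model(
            cohort, original, v, ridge=ridge, slope_on_full_lp=slope_on_full_lp
        )
        for v in UPDATE_VARIANTS
    }
    order = ("original", "calibration_in_the_large", "logistic_calibration")
    tests = tuple(lr_test(models["revision"], models[v]) for v in order)
    selected = "revision"
    for variant, test in zip(order, tests):
        if test.p_value >= alpha:
            selected = variant
            break
    return ClosedTestOutcome(selected=selected, tests=tests, alpha=alpha, models=models)
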