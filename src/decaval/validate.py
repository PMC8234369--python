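"""Optimism-corrected internal validation by the bootstrap.

Apparent performance of a model evaluated on its own training cohort is
optimistic.  The Harrell bootstrap estimates the optimism directly: refit
the model on each resample, and average the difference between its
performance on the resample (where it is again optimistic) and on the
original cohort (where it is honestly tested).  The corrected estimate is
the apparent value minus this mean optimism; percentile intervals over the
bootstrap performances give 95% CIs.

Model comparisons (continuous NRI, IDI) are bootstrapped jointly — both
models are refit on every resample — so each comparison is internally
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .metrics import (
    auc,
    brier_score,
    calibration_curve,
    calibration_intercept_slope,
    emax_ici,
    idi,
    nri_continuous,
)
from .model import CoefficientSet
from .updating import (
    EXTENDED_VARIANTS,
    UPDATE_VARIANTS,
    FittedModel,
    _as_frame,
    fit_extended_model,
    fit_update_model,
)

__all__ = [
    "DEFAULT_METRICS",
    "COMPARISON_METRICS",
    "ModelSpec",
    "MetricResult",
    "MetricReport",
    "bootstrap_validate",
]

DEFAULT_METRICS = ("brier", "auc", "intercept", "slope", "e_max", "ici")
COMPARISON_METRICS = ("nri_event", "nri_nonevent", "nri", "idi")


@dataclass(frozen=True)
class ModelSpec:
    """How to (re)fit a model variant on a cohort.

    Update variants (original / calibration_in_the_large /
    logistic_calibration / revision) require the original coefficient set;
    extended variants (continuous / complete) are plain refits.
    """

    variant: str
    original: CoefficientSet | None = None
    ridge: bool = False

    def fit(self, cohort) -> FittedModel:
        df = _as_frame(cohort)
        if self.variant in UPDATE_VARIANTS:
            if self.original is None:
                raise ValueError(
                    f"update variant {self.variant!r} requires the original "
                    "coefficient set"
                )
            return fit_update_model(df, self.original, self.variant, ridge=self.ridge)
        if self.variant in EXTENDED_VARIANTS:
            return fit_extended_model(df, self.variant, ridge=self.ridge)
        raise ValueError(f"unknown model variant {self.variant!r}")


@dataclass(frozen=True)
class MetricResult:
    apparent: float
    optimism: float
    corrected: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MetricReport:
    """Bootstrap validation report for one model (plus optional comparison)."""

    model_variant: str
    metrics: Mapping[str, MetricResult]
    B: int
    seed: int
    n_redraws: int
    comparison_variant: str | None = None
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": name,
                "apparent": r.apparent,
                "optimism": r.optimism,
                "corrected": r.corrected,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for name, r in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _clip_probs(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-10, 1.0 - 1e-10)


def _evaluate(
    p: np.ndarray,
    y: np.ndarray,
    metric_set: Sequence[str],
    span: float,
    p_old: np.ndarray | None = None,
) -> dict[str, float]:
    p = _clip_probs(np.asarray(p, dtype=float))
    vals: dict[str, float] = {}
    if "brier" in metric_set:
        vals["brier"] = brier_score(p, y)
    if "auc" in metric_set:
        vals["auc"] = auc(p, y)
    if "intercept" in metric_set or "slope" in metric_set:
        intercept, slope = calibration_intercept_slope(p, y)
        if "intercept" in metric_set:
            vals["intercept"] = intercept
        if "slope" in metric_set:
            vals["slope"] = slope
    if "e_max" in metric_set or "ici" in metric_set:
        curve = calibration_curve(p, y, span=span)
        e_max, ici_val = emax_ici(curve, p, y)
        if "e_max" in metric_set:
            vals["e_max"] = e_max
        if "ici" in metric_set:
            vals["ici"] = ici_val
    if p_old is not None:
        p_old = _clip_probs(np.asarray(p_old, dtype=float))
        if any(m in metric_set for m in ("nri_event", "nri_nonevent", "nri")):
            ev, ne, tot = nri_continuous(p, p_old, y)
            vals.update(nri_event=ev, nri_nonevent=ne, nri=tot)
        if "idi" in metric_set:
            vals["idi"] = idi(p, p_old, y)
    return vals


def bootstrap_validate(
    cohort,
    model_spec: ModelSpec,
    metric_set: Sequence[str] | None = None,
    B: int = 500,
    seed: int = 0,
    comparison: ModelSpec | None = None,
    stratified: bool = False,
    span: float = 0.75,
    ci_method: str = "boot_apparent",
    index_sampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
) -> MetricReport:
    """Harrell-style optimism correction with percentile 95% CIs.

    For each of ``B`` resamples (with replacement, same n) the model — and
    the comparison model, if any — is refit on the resample; each metric
    is computed on the resample (bootstrap performance) and on the
    original cohort (test performance); their difference is the optimism.
    The corrected value is ``apparent - mean(optimism)`` and the CI holds
    the 2.5/97.5 percentiles of the bootstrap performances.  Resamples
    with a single outcome class are redrawn and counted; the whole report
    is a pure function of its inputs and ``seed``.

    ``ci_method`` chooses the percentile population: ``"boot_apparent"``
    (default; the B bootstrap-sample performances) or ``"corrected"``
    (the B per-resample corrected values ``apparent - optimism_b``, useful
    for metrics whose bootstrap apparent value is degenerate, such as the
    calibration slope of a freshly refit model, which is identically 1).

    ``index_sampler(rng, n, b)`` overrides resample-index generation (a
    testing hook, e.g. to force the identity resample).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if ci_method not in ("boot_apparent", "corrected"):
        raise ValueError("ci_method must be 'boot_apparent' or 'corrected'")
    df = _as_frame(cohort).reset_index(drop=True)
    y = df["decannulated"].to_numpy(dtype=float)
    n = len(df)

    if metric_set is None:
        metric_set = DEFAULT_METRICS + (COMPARISON_METRICS if comparison else ())
    metric_set = tuple(metric_set)

    fit_app = model_spec.fit(df)
    p_app = fit_app.predict(df)
    old_app = comparison.fit(df).predict(df) if comparison else None
    apparent = _evaluate(p_app, y, metric_set, span, p_old=old_app)

    rng = np.random.default_rng(seed)
    ev_idx = np.flatnonzero(y == 1)
    ne_idx = np.flatnonzero(y == 0)

    boot_vals: dict[str, list[float]] = {m: [] for m in apparent}
    optimisms: dict[str, list[float]] = {m: [] for m in apparent}
    n_redraws = 0
    warnings: list[str] = []
    attempts = 0
    done = 0
    while done < B:
        attempts += 1
        if attempts > 10 * B:
            raise DegenerateDataError(
                f"exhausted {attempts} bootstrap draws with degenerate "
                "single-class resamples; cohort too small or too unbalanced"
            )
        if index_sampler is not None:
            idx = np.asarray(index_sampler(rng, n, done))
        elif stratified:
            idx = np.concatenate(
                [
                    rng.choice(ev_idx, size=len(ev_idx), replace=True),
                    rng.choice(ne_idx, size=len(ne_idx), replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
        y_b = y[idx]
        if y_b.min() == y_b.max():
            n_redraws += 1
            continue
        df_b = df.iloc[idx].reset_index(drop=True)

        fit_b = model_spec.fit(df_b)
        p_boot = fit_b.predict(df_b)
        p_test = fit_b.predict(df)
        if comparison is not None:
            old_b = comparison.fit(df_b)
            old_boot = old_b.predict(df_b)
            old_test = old_b.predict(df)
        else:
            old_boot = old_test = None
        boot = _evaluate(p_boot, y_b, metric_set, span, p_old=old_boot)
        test = _evaluate(p_test, y, metric_set, span, p_old=old_test)
        for m in apparent:
            boot_vals[m].append(boot[m])
            optimisms[m].append(boot[m] - test[m])
        done += 1

    if n_redraws:
        warnings.append(f"{n_redraws} single-class resample(s) redrawn")

    results = {}
    for m, app in apparent.items():
        mean_opt = float(np.mean(optimisms[m]))
        if ci_method == "boot_apparent":
            ci_pop = np.asarray(boot_vals[m])
        else:
            ci_pop = app - np.asarray(optimisms[m])
        lo, hi = np.percentile(ci_pop, [2.5, 97.5])
        results[m] = MetricResult(
            apparent=float(app),
            optimism=float(mean_opt),
            corrected=float(app - mean_opt),
            ci_low=float(lo),
            ci_high=float(hi),
        )
    return MetricReport(
        model_variant=model_spec.variant,
        metrics=results,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
        comparison_variant=comparison.variant if comparison else None,
        warnings=tuple(warnings),
    )
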