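"""End-to-end study replication: cohort -> closed test -> validated metrics.

``run_pipeline`` chains the package's stages on one configuration: obtain a
cohort (synthetic or CSV), summarize it, run the closed testing update of
the original model, fit the extended (continuous / complete) models,
bootstrap-validate every evaluated model — with reclassification metrics
computed against the selected update model — and write tabular artifacts
plus a JSON manifest.  Reruns with the same configuration and seed
reproduce every artifact byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .model import (
    COUGH_LEVELS,
    PATHOGENESIS_LEVELS,
    CoefficientSet,
    read_coefficients,
    synthetic_decapret_model,
    write_coefficients,
)
from .simulate import (
    CohortTable,
    ScreeningCounts,
    SimulationConfig,
    generate_cohort,
    summarize_cohort,
)
from .updating import closed_test_select
from .validate import ModelSpec, bootstrap_validate
from .metrics import calibration_curve

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "write_cohort"]

_REQUIRED_COLUMNS = CohortTable.COLUMNS
_BINARY_COLUMNS = ("female", "saliva_aspiration", "vegetative_status", "decannulated")


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort table as CSV with the documented header."""
    cohort.validate()
    cohort.data[list(_REQUIRED_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> CohortTable:
    """Read and validate a patient-level CSV (complete cases only).

    Errors name the offending column and 1-based data row, and reject any
    file with missing values, out-of-enumeration categories, or
    out-of-range covariates.
    """
    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing required column(s) {sorted(missing)}")
    df = df[list(_REQUIRED_COLUMNS)]
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        raise ValidationError(
            f"cohort CSV has {int(incomplete.sum())} incomplete row(s); "
            "complete cases are required"
        )

    def _bad_rows(mask) -> str:
        rows = (np.flatnonzero(mask) + 1).tolist()
        shown = ", ".join(map(str, rows[:5]))
        return f"row(s) {shown}{'...' if len(rows) > 5 else ''}"

    for col, levels in (("cough_class", COUGH_LEVELS), ("pathogenesis", PATHOGENESIS_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            first = df.loc[bad, col].iloc[0]
            raise ValidationError(
                f"{col} value {first!r} at {_bad_rows(bad)} not among allowed "
                f"levels {levels}"
            )
    for col in _BINARY_COLUMNS:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            raise ValidationError(f"{col} must be coded 0/1; invalid at {_bad_rows(bad)}")
    checks = (
        ("age_years", df["age_years"] < 18, ">= 18"),
        ("icu_los_days", ~((df["icu_los_days"] > 0) & (df["icu_los_days"] <= 90)), "in (0, 90]"),
        ("crs_r", ~df["crs_r"].between(0, 23), "in [0, 23]"),
    )
    for col, bad, rule in checks:
        if bad.any():
            raise ValidationError(f"{col} must be {rule}; invalid at {_bad_rows(bad)}")
    df = df.assign(crs_r=df["crs_r"].astype(int))
    for col in _BINARY_COLUMNS:
        df[col] = df[col].astype(int)
    return CohortTable(data=df.reset_index(drop=True), provenance=f"file:{path}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` / ``cohort_path`` supplies the cohort.
    ``original_coefficients`` points to a coefficient JSON file; when
    omitted, the shipped synthetic stand-in set is used (and recorded as
    such in the manifest).  ``models`` lists what to validate:
    ``revision_selected`` means "whichever variant the closed test picks".
    """

    output_dir: str
    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    original_coefficients: str | None = None
    alpha: float = 0.05
    B: int = 500
    seed: int = 0
    models: tuple[str, ...] = ("revision_selected", "continuous", "complete")
    span: float = 0.75
    ridge: bool = False
    stratified: bool = False

    def validate(self) -> None:
        if (self.simulation is None) == (self.cohort_path is None):
            raise ValidationError(
                "exactly one of 'simulation' and 'cohort_path' must be set"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        known = {"revision_selected", "continuous", "complete"}
        bad = set(self.models) - known
        if bad:
            raise ValidationError(f"unknown model request(s) {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        source = raw.pop("input", {})
        sim = source.get("synthetic")
        kwargs = {
            "output_dir": raw["output_dir"],
            "simulation": SimulationConfig.from_dict(sim) if sim is not None else None,
            "cohort_path": source.get("cohort_csv"),
        }
        for key in ("original_coefficients", "alpha", "B", "seed", "span", "ridge", "stratified"):
            if key in raw:
                kwargs[key] = raw[key]
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        return cls(**kwargs)


def _derived_seeds(seed: int, k: int) -> list[int]:
    # independent child streams, each representable as a small positive int
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(k)]


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return _StageContext()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full replication; returns the manifest (also written).

    Artifacts (all under ``config.output_dir``): ``cohort.csv``,
    ``cohort_summary.tsv``, ``original_coefficients.json``,
    ``closed_test.tsv``, ``metrics.tsv``, ``calibration_<model>.csv`` and
    ``calibration_deciles_<model>.csv`` per evaluated model, and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_cohort, seed_boot = _derived_seeds(config.seed, 2)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": {"cohort": seed_cohort, "bootstrap": seed_boot},
        "alpha": config.alpha,
        "B": config.B,
        "screening": {
            "initial": ScreeningCounts().initial,
            "excluded_by_criteria": ScreeningCounts().excluded_by_criteria,
            "deaths_during_rehabilitation": ScreeningCounts().deaths_during_rehabilitation,
            "analyzed": ScreeningCounts().analyzed,
        },
        "artifacts": [],
        "warnings": [],
    }

    with _stage("cohort"):
        if config.simulation is not None:
            sim = replace(config.simulation, seed=seed_cohort)
            cohort = generate_cohort(sim)
            manifest["input"] = {"synthetic": sim.to_dict(), "config_hash": sim.hash()}
        else:
            cohort = read_cohort(config.cohort_path)
            manifest["input"] = {"cohort_csv": str(config.cohort_path)}
        manifest["n_patients"] = len(cohort)
        manifest["prevalence"] = float(cohort.outcome.mean())
        write_cohort(cohort, out / "cohort.csv")
        manifest["artifacts"].append("cohort.csv")
        summarize_cohort(cohort).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        manifest["artifacts"].append("cohort_summary.tsv")

    with _stage("original_coefficients"):
        if config.original_coefficients is not None:
            original = read_coefficients(config.original_coefficients)
        else:
            original = synthetic_decapret_model()
        write_coefficients(original, out / "original_coefficients.json")
        manifest["artifacts"].append("original_coefficients.json")
        manifest["original_provenance"] = original.provenance

    with _stage("closed_test"):
        outcome = closed_test_select(
            cohort, original, alpha=config.alpha, ridge=config.ridge
        )
        rows = [
            {
                "comparison": t.comparison,
                "df": t.df,
                "chi2": t.statistic,
                "p_value": t.p_value,
            }
            for t in outcome.tests
        ]
        pd.DataFrame(rows).to_csv(out / "closed_test.tsv", sep="\t", index=False)
        manifest["artifacts"].append("closed_test.tsv")
        manifest["closed_test"] = {
            "selected": outcome.selected,
            "alpha": outcome.alpha,
            "df": [t.df for t in outcome.tests],
        }

    with _stage("validation"):
        selected_spec = ModelSpec(
            variant=outcome.selected, original=original, ridge=config.ridge
        )
        specs: list[tuple[str, ModelSpec, ModelSpec | None]] = []
        for request in config.models:
            if request == "revision_selected":
                specs.append((outcome.selected, selected_spec, None))
            else:
                specs.append(
                    (request, ModelSpec(variant=request, ridge=config.ridge), selected_spec)
                )
        frames = []
        df = cohort.data
        y = cohort.outcome
        for i, (label, spec, comparison) in enumerate(specs):
            report = bootstrap_validate(
                cohort,
                spec,
                B=config.B,
                seed=seed_boot + i,
                comparison=comparison,
                stratified=config.stratified,
                span=config.span,
            )
            frame = report.to_frame()
            frame.insert(0, "model", label)
            if comparison is not None:
                frame["compared_to"] = comparison.variant
            frames.append(frame)
            manifest["warnings"].extend(f"{label}: {w}" for w in report.warnings)

            fit = spec.fit(df)
            p = np.clip(fit.predict(df), 1e-10, 1 - 1e-10)
            curve = calibration_curve(p, y, span=config.span)
            pd.DataFrame(
                {"predicted": curve.points, "smoothed_observed": curve.smoothed}
            ).to_csv(out / f"calibration_{label}.csv", index=False)
            curve.deciles.to_csv(out / f"calibration_deciles_{label}.csv", index=False)
            manifest["artifacts"] += [
                f"calibration_{label}.csv",
                f"calibration_deciles_{label}.csv",
            ]
        metrics = pd.concat(frames, ignore_index=True)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        manifest["artifacts"].append("metrics.tsv")
        manifest["evaluated_models"] = [label for label, _, _ in specs]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
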