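"""End-to-end orchestration: cohort -> anthropometry -> LMS curves ->
percentile tables and decline summaries -> stepwise regression -> equation
agreement.  The result is a ReportBundle whose content is completely
determined by the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import body_density, body_fat_percent, compute_bmi
from .cohort import generate_cohort
from .config import CohortConfig
from .io import read_cohort_csv, write_cohort_csv
from .lms import (
    DEFAULT_ALPHAS,
    DeclineSummary,
    LMSCurve,
    SmoothingSpec,
    decline_summary,
    fit_lms_curve,
    percentile_table,
)
from .prediction import (
    AgreementStats,
    RegressionModel,
    bland_altman,
    evaluate_equation,
    stepwise_select,
)

__all__ = ["ReportBundle", "run_pipeline", "MEASURES"]

log = logging.getLogger("hrcentiles")

#: Heart-rate measures receiving reference curves.
MEASURES = ("mhr_bpm", "rhr_bpm")

#: Percentile series summarised for age-decline (P3, median, P97).
DECLINE_ALPHAS = (0.03, 0.50, 0.97)

#: Stepwise candidate predictors offered to the MHR regression.
CANDIDATES = ("age", "bmi", "height_m", "body_mass_kg", "body_fat_pct", "rhr_bpm")


@dataclass(frozen=True)
class ReportBundle:
    """Machine-readable pipeline output mirroring the reference-study tables."""

    cohort: pd.DataFrame
    lms_curves: dict[str, LMSCurve]
    percentile_tables: dict[str, pd.DataFrame]
    decline_summaries: dict[str, dict[str, DeclineSummary]]
    models: list[RegressionModel]
    selection_trace: list[str]
    agreement: dict[str, AgreementStats]
    provenance: dict


def _stage(name: str, t0: float, shape) -> None:
    log.info("stage=%s shape=%s elapsed=%.3fs", name, shape, time.perf_counter() - t0)


def run_pipeline(
    config: CohortConfig | None = None,
    cohort_path=None,
    smoothing: SmoothingSpec | None = None,
    alphas=DEFAULT_ALPHAS,
    out_dir=None,
) -> ReportBundle:
    """Run the full analysis from a generative config or an existing cohort CSV.

    Exactly one of ``config`` / ``cohort_path`` provides the cohort (when both
    are given the CSV wins and the config is recorded for provenance only).
    When ``out_dir`` is given the bundle is written there as CSV tables plus
    a YAML summary.
    """
    t0 = time.perf_counter()
    if config is None and cohort_path is None:
        raise ValueError("provide a CohortConfig or a cohort CSV path")
    if cohort_path is not None:
        cohort = read_cohort_csv(cohort_path)
        source = str(cohort_path)
    else:
        cohort = generate_cohort(config)
        source = "generated"
    _stage("cohort", t0, cohort.shape)

    # anthropometric derivations
    t1 = time.perf_counter()
    work = cohort.copy()
    work["bmi"] = compute_bmi(work["body_mass_kg"], work["height_m"])
    sum_sf = (
        work["skinfold_triceps_mm"]
        + work["skinfold_biceps_mm"]
        + work["skinfold_subscapular_mm"]
        + work["skinfold_suprailiac_mm"]
    )
    work["body_fat_pct"] = body_fat_percent(body_density(sum_sf, work["age"]))
    _stage("anthropometry", t1, work.shape)

    # LMS reference curves
    t2 = time.perf_counter()
    curves: dict[str, LMSCurve] = {}
    tables: dict[str, pd.DataFrame] = {}
    declines: dict[str, dict[str, DeclineSummary]] = {}
    for measure in MEASURES:
        curve = fit_lms_curve(work, measure, smoothing_spec=smoothing)
        curves[measure] = curve
        tables[measure] = percentile_table(curve, alphas)
        declines[measure] = {}
        for al in DECLINE_ALPHAS:
            col = f"P{al * 100:g}"
            if col in tables[measure].columns:
                declines[measure][col] = decline_summary(tables[measure][col].to_numpy())
    _stage("lms", t2, {m: c.to_frame().shape for m, c in curves.items()})

    # stepwise MHR regression
    t3 = time.perf_counter()
    models, trace = stepwise_select(work["mhr_bpm"], work[list(CANDIDATES)])
    _stage("stepwise", t3, [m.predictor_names for m in models])

    # agreement with the fitted model and the reference equations
    t4 = time.perf_counter()
    measured = work["mhr_bpm"].to_numpy()
    agreement: dict[str, AgreementStats] = {}
    if models:
        agreement["model1"] = bland_altman(measured, models[0].predict(work))
    agreement["fox"] = bland_altman(measured, evaluate_equation("fox", work["age"]))
    agreement["tanaka"] = bland_altman(measured, evaluate_equation("tanaka", work["age"]))
    _stage("agreement", t4, list(agreement))

    provenance = {
        "version": __version__,
        "source": source,
        "seed": None if config is None else config.seed,
        "config": None if config is None else config.model_dump(mode="json"),
        "alphas": [float(a) for a in alphas],
        "smoothing": dataclasses.asdict(smoothing or SmoothingSpec()),
    }
    bundle = ReportBundle(
        cohort=work,
        lms_curves=curves,
        percentile_tables=tables,
        decline_summaries=declines,
        models=models,
        selection_trace=trace,
        agreement=agreement,
        provenance=provenance,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write the bundle as CSV tables plus one YAML summary (full precision)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(bundle.cohort, out / "cohort.csv")
    for measure, curve in bundle.lms_curves.items():
        curve.to_frame().to_csv(out / f"lms_{measure}.csv", float_format="%.17g")
        bundle.percentile_tables[measure].to_csv(
            out / f"percentiles_{measure}.csv", float_format="%.17g"
        )
    decl_rows = []
    for measure, per_pct in bundle.decline_summaries.items():
        for pct, ds in per_pct.items():
            decl_rows.append({"measure": measure, "percentile": pct, **dataclasses.asdict(ds)})
    pd.DataFrame(decl_rows).to_csv(out / "declines.csv", index=False, float_format="%.17g")

    summary = {
        "provenance": bundle.provenance,
        "models": [
            {
                "predictors": list(m.predictor_names),
                "coefficients": {
                    "intercept": m.intercept,
                    **dict(zip(m.predictor_names, m.coefficients[1:])),
                },
                "r_squared": m.r_squared,
                "see": m.see,
                "residual_range": list(m.residual_range),
                "n": m.n,
            }
            for m in bundle.models
        ],
        "selection_trace": bundle.selection_trace,
        "agreement": {
            name: dataclasses.asdict(st) for name, st in bundle.agreement.items()
        },
        "decline_summaries": {
            measure: {pct: dataclasses.asdict(ds) for pct, ds in per.items()}
            for measure, per in bundle.decline_summaries.items()
        },
    }
    with open(out / "summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)


def round_report(value: float, ndigits: int = 2) -> float:
    """Half-away-from-zero rounding used only at the reporting layer."""
    q = 10.0**ndigits
    return float(np.copysign(np.floor(abs(value) * q + 0.5) / q, value))
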