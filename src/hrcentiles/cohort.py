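"""Synthetic adolescent-athlete cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so LMS curve fitting and the regression comparisons are testable
without any external data.  Two generative modes per heart-rate measure:

* linear mode (default): an age-linear mean plus Gaussian residual noise
  (MHR uses the published model coefficients and residual SD; RHR linearly
  interpolates the published endpoint medians);
* BCCG mode: per-age Box-Cox Cole-Green draws with (L, M, S) linearly
  interpolated between configured anchors.

All randomness flows from the master seed through labelled substreams (see
``hrcentiles._rng``), so every stage's draws are independent and stable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._rng import substream
from .anthropometry import compute_bmi
from .config import SKINFOLD_SITES, BCCGAnchor, CohortConfig

__all__ = [
    "PlayerRecord",
    "COHORT_COLUMNS",
    "sample_ages",
    "generate_bccg_sample",
    "generate_cohort",
]

#: Canonical cohort column order (trainability is optional and appended last).
COHORT_COLUMNS = (
    "age",
    "height_m",
    "body_mass_kg",
    "skinfold_triceps_mm",
    "skinfold_biceps_mm",
    "skinfold_subscapular_mm",
    "skinfold_suprailiac_mm",
    "rhr_bpm",
    "mhr_bpm",
)


class PlayerRecord(BaseModel):
    """One athlete's age, anthropometrics and heart rates.

    ``trainability`` is an opaque optional covariate carried through for
    completeness; it enters no computation in this package.
    """

    model_config = ConfigDict(frozen=True)

    age: int
    height_m: float = Field(gt=0.0)
    body_mass_kg: float = Field(gt=0.0)
    skinfold_triceps_mm: float = Field(gt=0.0)
    skinfold_biceps_mm: float = Field(gt=0.0)
    skinfold_subscapular_mm: float = Field(gt=0.0)
    skinfold_suprailiac_mm: float = Field(gt=0.0)
    rhr_bpm: float = Field(gt=0.0)
    mhr_bpm: float
    trainability: Optional[float] = None

    @model_validator(mode="after")
    def _mhr_above_rhr(self) -> "PlayerRecord":
        if not (self.mhr_bpm > self.rhr_bpm):
            raise ValueError(
                f"mhr_bpm ({self.mhr_bpm}) must exceed rhr_bpm ({self.rhr_bpm})"
            )
        return self


def sample_ages(n: int, age_levels, proportions, seed: int) -> np.ndarray:
    """Draw ``n`` integer ages categorically by the configured proportions."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    levels = np.asarray(age_levels, dtype=int)
    p = np.asarray(proportions, dtype=float)
    if levels.size != p.size:
        raise ValueError("age_levels and proportions must have equal length")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = substream(seed, "ages")
    return rng.choice(levels, size=n, p=p / p.sum())


def generate_bccg_sample(
    L: float, M: float, S: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from the Box-Cox Cole-Green law with parameters (L, M, S).

    z ~ N(0,1); x = M*(1 + L*S*z)^(1/L) for L != 0, M*exp(S*z) for L == 0.
    Draws with 1 + L*S*z <= 0 (possible only for L != 0) are rejected and
    redrawn, truncating the far tail of z.
    """
    if M <= 0 or S <= 0:
        raise ValueError(f"M and S must be positive (M={M}, S={S})")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "bccg")
    out = np.empty(n)
    filled = 0
    while filled < n:
        z = rng.standard_normal(n - filled)
        if abs(L) < 1e-7:
            x = M * np.exp(S * z)
        else:
            base = 1.0 + L * S * z
            ok = base > 0
            z, base = z[ok], base[ok]
            x = M * base ** (1.0 / L)
        out[filled : filled + x.size] = x
        filled += x.size
    return out


def _interp_anchors(anchors: tuple[BCCGAnchor, ...], age: int) -> tuple[float, float, float]:
    """Linearly interpolate (L, M, S) between anchors at an integer age."""
    ages = np.array([a.age for a in anchors], dtype=float)
    L = float(np.interp(age, ages, [a.L for a in anchors]))
    M = float(np.interp(age, ages, [a.M for a in anchors]))
    S = float(np.interp(age, ages, [a.S for a in anchors]))
    return L, M, S


def _draw_anthro(config: CohortConfig, ages: np.ndarray, rng: np.random.Generator) -> dict:
    """Age-linear Gaussian anthropometrics, floored to stay physiologic."""
    ap = config.anthro_params
    cols = {}
    for name, var in [("height_m", ap.height_m), ("body_mass_kg", ap.body_mass_kg)]:
        mean = var.mean_at_11 + var.slope_per_year * (ages - 11.0)
        cols[name] = np.maximum(mean + var.sd * rng.standard_normal(ages.size), var.floor)
    for site in SKINFOLD_SITES:
        var = ap.skinfolds_mm[site]
        mean = var.mean_at_11 + var.slope_per_year * (ages - 11.0)
        cols[f"skinfold_{site}_mm"] = np.maximum(
            mean + var.sd * rng.standard_normal(ages.size), var.floor
        )
    return cols


def _draw_measure_bccg(
    anchors: tuple[BCCGAnchor, ...],
    ages: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty(ages.size)
    for age in np.unique(ages):
        idx = np.flatnonzero(ages == age)
        L, M, S = _interp_anchors(anchors, int(age))
        out[idx] = generate_bccg_sample(L, M, S, idx.size, rng)
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort as a DataFrame of validated player rows.

    Column layout follows :data:`COHORT_COLUMNS`.  Identical configs (same
    seed) produce bit-identical frames.
    """
    seed = config.seed
    ages = sample_ages(config.n_players, config.age_levels, config.age_proportions, seed)
    cols: dict[str, np.ndarray] = {"age": ages}
    cols.update(_draw_anthro(config, ages.astype(float), substream(seed, "anthro")))

    anchors = config.bccg_anchors or {}

    # MHR: BCCG anchors override the linear model
    if "mhr_bpm" in anchors:
        cols["mhr_bpm"] = _draw_measure_bccg(
            anchors["mhr_bpm"], ages, substream(seed, "mhr")
        )
    else:
        mean = config.mhr_intercept + config.mhr_age_slope * ages
        if config.mhr_bmi_slope != 0.0:
            bmi = compute_bmi(cols["body_mass_kg"], cols["height_m"])
            mean = mean + config.mhr_bmi_slope * bmi
        noise = config.mhr_residual_sd * substream(seed, "mhr").standard_normal(ages.size)
        cols["mhr_bpm"] = mean + noise

    # RHR: BCCG anchors override endpoint-interpolated linear mode
    if "rhr_bpm" in anchors:
        cols["rhr_bpm"] = _draw_measure_bccg(
            anchors["rhr_bpm"], ages, substream(seed, "rhr")
        )
    else:
        a_x = [a for a, _ in config.rhr_anchors]
        a_y = [m for _, m in config.rhr_anchors]
        mean = np.interp(ages, a_x, a_y)
        rng = substream(seed, "rhr")
        rhr = mean + config.rhr_residual_sd * rng.standard_normal(ages.size)
        # redraw the (vanishingly rare) rows violating 0 < rhr < mhr
        bad = (rhr <= 0) | (rhr >= cols["mhr_bpm"])
        while np.any(bad):
            rhr[bad] = mean[bad] + config.rhr_residual_sd * rng.standard_normal(
                int(bad.sum())
            )
            bad = (rhr <= 0) | (rhr >= cols["mhr_bpm"])
        cols["rhr_bpm"] = rhr

    df = pd.DataFrame(cols, columns=list(COHORT_COLUMNS))
    df["age"] = df["age"].astype(int)
    return df
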