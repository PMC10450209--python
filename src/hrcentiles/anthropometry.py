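"""Anthropometric derived quantities: BMI, body density, body-fat percent.

Body density follows the four-skinfold (triceps + biceps + subscapular +
suprailiac) quadratic formula for adolescent males, and body fat converts
density via the Siri relation 4.95/D - 4.50, reported on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnthroResult", "compute_bmi", "body_density", "body_fat_percent", "anthro_result"]


@dataclass(frozen=True)
class AnthroResult:
    """Derived anthropometrics for one athlete."""

    bmi: float  # kg/m^2
    density: float  # g/cm^3
    body_fat_pct: float  # percent, 0-100 in physiologic range
    sum_skinfolds: float  # mm


def compute_bmi(body_mass_kg, height_m):
    """Body-mass index: mass (kg) divided by squared height (m^2)."""
    mass = np.asarray(body_mass_kg, dtype=float)
    height = np.asarray(height_m, dtype=float)
    if np.any(mass <= 0) or np.any(height <= 0):
        raise ValueError("body mass and height must be positive")
    out = mass / height**2
    return float(out) if out.ndim == 0 else out


def body_density(sum_skinfolds_mm, age_years):
    """Body density (g/cm^3) from the four-skinfold sum and age.

    D = 1.0994921 - 0.0009929*s + 0.0000023*s^2 - 0.0001392*age, with s the
    skinfold sum in mm.  Strictly decreasing in s over the physiologic range
    (the quadratic's vertex lies near s = 216 mm).
    """
    s = np.asarray(sum_skinfolds_mm, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(s <= 0) or np.any(age <= 0):
        raise ValueError("skinfold sum and age must be positive")
    out = 1.0994921 - 0.0009929 * s + 0.0000023 * s**2 - 0.0001392 * age
    return float(out) if out.ndim == 0 else out


def body_fat_percent(density):
    """Body fat on the percent scale via Siri: 100 * (4.95/D - 4.50)."""
    d = np.asarray(density, dtype=float)
    if np.any(d <= 0):
        raise ValueError("density must be positive")
    out = 100.0 * (4.95 / d - 4.50)
    return float(out) if out.ndim == 0 else out


def anthro_result(
    body_mass_kg: float,
    height_m: float,
    skinfolds_mm,
    age_years: float,
) -> AnthroResult:
    """Bundle BMI, density and body-fat percent for one athlete.

    ``skinfolds_mm`` holds exactly the four site measurements; a missing or
    extra site is an error, not an imputation.
    """
    sf = np.asarray(skinfolds_mm, dtype=float)
    if sf.shape != (4,):
        raise ValueError(f"exactly four skinfold sites required, got shape {sf.shape}")
    s = float(sf.sum())
    d = body_density(s, age_years)
    return AnthroResult(
        bmi=compute_bmi(body_mass_kg, height_m),
        density=d,
        body_fat_pct=body_fat_percent(d),
        sum_skinfolds=s,
    )
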