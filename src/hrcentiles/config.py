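"""Cohort-generation configuration.

The defaults encode the study conditions of the reference cohort the package
emulates: 801 male adolescent soccer players, integer ages 11-18 with the
published age-group proportions, maximum heart rate (MHR) following the
age-linear model ``MHR = 225.08 - 1.55*age`` with residual SD 5.22 bpm, and
resting heart rate (RHR) declining from a median of 73.86 bpm at age 11 to
63.64 bpm at age 18.
"""

from __future__ import annotations

import math
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "AnthroVariable",
    "AnthroParams",
    "BCCGAnchor",
    "CohortConfig",
    "default_config",
    "SKINFOLD_SITES",
]

#: The four skinfold sites entering the body-density formula, in canonical order.
SKINFOLD_SITES = ("triceps", "biceps", "subscapular", "suprailiac")

#: Published age-group proportions for ages 11..18 (fractions of n=801).
DEFAULT_AGE_PROPORTIONS = (
    0.1223, 0.1061, 0.1361, 0.1348, 0.1311, 0.1286, 0.1099, 0.1311,
)


class AnthroVariable(BaseModel):
    """Age-linear mean with Gaussian noise for one anthropometric variable.

    mean(age) = mean_at_11 + slope_per_year * (age - 11); draws are clipped
    below at ``floor`` to keep physically meaningful values positive.
    """

    model_config = ConfigDict(frozen=True)

    mean_at_11: float
    slope_per_year: float = 0.0
    sd: float = Field(ge=0.0)
    floor: float = 0.01

    def mean(self, age: float) -> float:
        return self.mean_at_11 + self.slope_per_year * (age - 11.0)


class AnthroParams(BaseModel):
    """Per-variable generative parameters for height, mass and skinfolds."""

    model_config = ConfigDict(frozen=True)

    height_m: AnthroVariable = AnthroVariable(
        mean_at_11=1.45, slope_per_year=0.046, sd=0.07, floor=0.9
    )
    body_mass_kg: AnthroVariable = AnthroVariable(
        mean_at_11=38.0, slope_per_year=4.5, sd=6.0, floor=20.0
    )
    skinfolds_mm: dict[str, AnthroVariable] = {
        "triceps": AnthroVariable(mean_at_11=9.0, slope_per_year=-0.25, sd=2.5, floor=1.0),
        "biceps": AnthroVariable(mean_at_11=5.5, slope_per_year=-0.15, sd=1.5, floor=1.0),
        "subscapular": AnthroVariable(mean_at_11=6.5, slope_per_year=0.10, sd=2.0, floor=1.0),
        "suprailiac": AnthroVariable(mean_at_11=6.0, slope_per_year=0.15, sd=2.0, floor=1.0),
    }

    @field_validator("skinfolds_mm")
    @classmethod
    def _all_sites(cls, v: dict[str, AnthroVariable]) -> dict[str, AnthroVariable]:
        missing = set(SKINFOLD_SITES) - set(v)
        if missing:
            raise ValueError(f"missing skinfold sites: {sorted(missing)}")
        return v


class BCCGAnchor(BaseModel):
    """One (age, L, M, S) anchor of a Box-Cox Cole-Green age trend."""

    model_config = ConfigDict(frozen=True)

    age: int
    L: float
    M: float = Field(gt=0.0)
    S: float = Field(gt=0.0)


class CohortConfig(BaseModel):
    """Full generative specification of a synthetic cohort.

    ``bccg_anchors`` maps a measure column (``"mhr_bpm"`` or ``"rhr_bpm"``)
    to a list of anchors; between anchors each of L, M, S is linearly
    interpolated in age.  When a measure has anchors they replace its default
    generative model for that measure.
    """

    model_config = ConfigDict(frozen=True)

    n_players: int = Field(default=801, gt=0)
    age_levels: tuple[int, ...] = tuple(range(11, 19))
    age_proportions: tuple[float, ...] = DEFAULT_AGE_PROPORTIONS
    mhr_intercept: float = 225.08
    mhr_age_slope: float = -1.55
    mhr_bmi_slope: float = 0.0
    mhr_residual_sd: float = Field(default=5.22, ge=0.0)
    rhr_anchors: tuple[tuple[int, float], ...] = ((11, 73.86), (18, 63.64))
    rhr_residual_sd: float = Field(default=5.8, ge=0.0)
    anthro_params: AnthroParams = AnthroParams()
    bccg_anchors: Optional[dict[str, tuple[BCCGAnchor, ...]]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if len(self.age_levels) != len(self.age_proportions):
            raise ValueError("age_levels and age_proportions must have equal length")
        if any(p < 0 for p in self.age_proportions):
            raise ValueError("age_proportions must be non-negative")
        if not math.isclose(sum(self.age_proportions), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"age_proportions must sum to 1 (got {sum(self.age_proportions)!r})"
            )
        if list(self.age_levels) != sorted(set(self.age_levels)):
            raise ValueError("age_levels must be strictly increasing")
        ages = [a for a, _ in self.rhr_anchors]
        if ages != sorted(set(ages)) or len(ages) < 2:
            raise ValueError("rhr_anchors need >= 2 strictly increasing ages")
        if any(m <= 0 for _, m in self.rhr_anchors):
            raise ValueError("rhr anchor medians must be positive")
        if self.bccg_anchors is not None:
            for measure, anchors in self.bccg_anchors.items():
                a_ages = [a.age for a in anchors]
                if a_ages != sorted(set(a_ages)) or len(a_ages) < 1:
                    raise ValueError(
                        f"bccg_anchors[{measure!r}] need strictly increasing ages"
                    )
                lo, hi = a_ages[0], a_ages[-1]
                uncovered = [a for a in self.age_levels if not (lo <= a <= hi)]
                if len(a_ages) > 1 and uncovered:
                    raise ValueError(
                        f"bccg_anchors[{measure!r}] do not cover ages {uncovered}"
                    )
        return self

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def default_config(**overrides) -> CohortConfig:
    """The study-default configuration, optionally with field overrides."""
    return CohortConfig(**overrides)
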