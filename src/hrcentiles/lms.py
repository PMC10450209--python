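"""LMS (Box-Cox Cole-Green) reference-curve engine.

The LMS method summarises an age-dependent reference distribution by three
curves: the Box-Cox power L (lambda, skewness), the median M (mu) and the
coefficient of variation S (sigma).  A measurement x at an age with
parameters (L, M, S) has z-score

    z = ((x/M)**L - 1) / (L*S)        (L != 0)
    z = ln(x/M) / S                   (L == 0)

and the centile curve at cumulative fraction alpha is the inverse map

    C_100a = M * (1 + L*S*z_a)**(1/L)     (L != 0)
    C_100a = M * exp(S * z_a)             (L == 0)

with z_a the standard-normal quantile of alpha.  Fitting is two-stage:
per-age-group maximum likelihood of the BCCG log-likelihood, then a cubic
smoothing spline across age for each of L, M and S with a configurable
equivalent degrees of freedom (edf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .smoothing import smoothing_spline

__all__ = [
    "LMSPoint",
    "LMSCurve",
    "PercentileSpec",
    "DeclineSummary",
    "SmoothingSpec",
    "bccg_percentile",
    "bccg_zscore",
    "bccg_loglik",
    "fit_bccg_group",
    "fit_lms_curve",
    "percentile_table",
    "decline_summary",
    "DEFAULT_ALPHAS",
]

#: Reported percentile set: P3, P10, P25, P50, P75, P90, P97.
DEFAULT_ALPHAS = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)

#: Below this |L| the exact log-normal (L=0) limit is used for continuity.
_L_EPS = 1e-7


@dataclass(frozen=True)
class LMSPoint:
    """Box-Cox Cole-Green parameters at one age: power L, median M, CV S."""

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not (self.M > 0):
            raise ValueError(f"M must be positive, got {self.M}")
        if not (self.S > 0):
            raise ValueError(f"S must be positive, got {self.S}")


@dataclass(frozen=True)
class PercentileSpec:
    """A centile identified by its fraction alpha and normal quantile z_alpha."""

    alpha: float
    z_alpha: float

    @classmethod
    def from_alpha(cls, alpha: float) -> "PercentileSpec":
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        return cls(alpha=alpha, z_alpha=float(stats.norm.ppf(alpha)))

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if abs(self.z_alpha - stats.norm.ppf(self.alpha)) > 1e-9:
            raise ValueError("z_alpha inconsistent with alpha")


@dataclass(frozen=True)
class SmoothingSpec:
    """Equivalent degrees of freedom for the across-age smoother of L, M, S.

    ``None`` for a component disables smoothing (the per-age estimates are
    kept as-is).  edf ranges from 2 (straight line) to the number of ages
    (interpolation).
    """

    edf_L: float | None = 3.0
    edf_M: float | None = 5.0
    edf_S: float | None = 3.0


@dataclass(frozen=True)
class LMSCurve:
    """One measure's fitted L, M, S sequences over an integer-age grid."""

    measure_name: str
    ages: tuple[int, ...]
    points: tuple[LMSPoint, ...]
    smoothing_spec: SmoothingSpec = field(default_factory=SmoothingSpec)

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.points):
            raise ValueError("one LMSPoint required per age")
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")

    def at(self, age: int) -> LMSPoint:
        try:
            return self.points[self.ages.index(age)]
        except ValueError:
            raise KeyError(f"age {age} not on the curve grid {self.ages}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": list(self.ages),
                "L": [p.L for p in self.points],
                "M": [p.M for p in self.points],
                "S": [p.S for p in self.points],
            }
        ).set_index("age")


@dataclass(frozen=True)
class DeclineSummary:
    """Year-on-year decline statistics of one percentile series."""

    mean_yearly_decline: float
    sd_yearly_decline: float
    overall_pct_change: float
    n_steps: int


# ---------------------------------------------------------------------------
# transform and inverse

def bccg_percentile(point: LMSPoint, spec: PercentileSpec | float) -> float:
    """Centile value C_100a = M(1 + L*S*z_a)^(1/L) at one age.

    ``spec`` may be a PercentileSpec or a bare alpha fraction.
    """
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec.from_alpha(float(spec))
    L, M, S, z = point.L, point.M, point.S, spec.z_alpha
    if abs(L) < _L_EPS:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0.0:
        raise ValueError(
            f"infeasible tail: 1 + L*S*z = {base:.6g} <= 0 at alpha={spec.alpha}"
            f" (L={L}, S={S})"
        )
    return float(M * base ** (1.0 / L))


def bccg_zscore(x: float, point: LMSPoint) -> float:
    """z-score of measurement ``x`` under (L, M, S); inverse of the centile map."""
    if not np.all(np.asarray(x) > 0):
        raise ValueError("measurements must be positive")
    L, M, S = point.L, point.M, point.S
    x = np.asarray(x, dtype=float)
    if abs(L) < _L_EPS:
        z = np.log(x / M) / S
    else:
        z = ((x / M) ** L - 1.0) / (L * S)
    return float(z) if z.ndim == 0 else z


# ---------------------------------------------------------------------------
# per-group maximum likelihood

def bccg_loglik(values: np.ndarray, L: float, M: float, S: float) -> float:
    """BCCG log-likelihood (additive constants dropped).

    Per observation: L*ln(x/M) - ln(S) - z^2/2, with z the BCCG z-score.
    Returns -inf when a z-score is undefined (the Box-Cox argument
    non-positive cannot occur for x, M > 0, but overflow can).
    """
    x = np.asarray(values, dtype=float)
    r = x / M
    if abs(L) < _L_EPS:
        z = np.log(r) / S
    else:
        z = (r**L - 1.0) / (L * S)
    ll = L * np.log(r) - np.log(S) - 0.5 * z**2
    total = float(np.sum(ll))
    return total if np.isfinite(total) else -np.inf


def fit_bccg_group(values) -> LMSPoint:
    """Maximum-likelihood (L, M, S) for one age group's measurements.

    Optimises over (L, ln M, ln S) with Nelder-Mead from the moment-based
    start (L=1, M=sample median, S=sample SD / median).

    Raises ValueError on fewer than 20 values, non-positive values, or
    (near-)constant input, and RuntimeError on optimizer failure.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError(f"need >= 20 values to fit a BCCG group, got {x.size}")
    if not np.all(x > 0):
        raise ValueError("all values must be positive")
    med = float(np.median(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0 or sd / med < 1e-12:
        raise ValueError("degenerate (constant) input: BCCG fit undefined")

    def nll(theta: np.ndarray) -> float:
        L, logM, logS = theta
        return -bccg_loglik(x, L, float(np.exp(logM)), float(np.exp(logS)))

    start = np.array([1.0, np.log(med), np.log(sd / med)])
    res = optimize.minimize(
        nll,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    if not res.success:
        raise RuntimeError(f"BCCG fit did not converge: {res.message}")
    L, logM, logS = res.x
    return LMSPoint(L=float(L), M=float(np.exp(logM)), S=float(np.exp(logS)))


# ---------------------------------------------------------------------------
# curve fitting across age

def fit_lms_curve(
    cohort: pd.DataFrame,
    measure: str,
    smoothing_spec: SmoothingSpec | None = None,
    age_column: str = "age",
) -> LMSCurve:
    """Two-stage LMS fit of ``measure`` against integer age.

    Stage 1: per-age-group ML estimates of (L, M, S).  Stage 2: each of the
    L, M and S sequences is smoothed across age by a cubic smoothing spline
    at the configured equivalent degrees of freedom (M on the log scale so
    the smoothed median stays positive).
    """
    spec = smoothing_spec if smoothing_spec is not None else SmoothingSpec()
    if measure not in cohort.columns:
        raise KeyError(f"measure column {measure!r} not in cohort")
    ages = sorted(int(a) for a in cohort[age_column].unique())
    raw: dict[str, list[float]] = {"L": [], "M": [], "S": []}
    for age in ages:
        grp = cohort.loc[cohort[age_column] == age, measure].to_numpy()
        try:
            pt = fit_bccg_group(grp)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"LMS group fit failed at age {age}: {exc}") from exc
        raw["L"].append(pt.L)
        raw["M"].append(pt.M)
        raw["S"].append(pt.S)

    a = np.asarray(ages, dtype=float)

    def smooth(y: list[float], edf: float | None, log_scale: bool) -> np.ndarray:
        arr = np.asarray(y, dtype=float)
        if edf is None or len(arr) < 3:
            return arr
        tr = np.log(arr) if log_scale else arr
        out = smoothing_spline(a, tr, edf=min(edf, len(arr)))
        return np.exp(out) if log_scale else out

    Ls = smooth(raw["L"], spec.edf_L, log_scale=False)
    Ms = smooth(raw["M"], spec.edf_M, log_scale=True)
    Ss = smooth(raw["S"], spec.edf_S, log_scale=True)
    points = tuple(
        LMSPoint(L=float(l), M=float(m), S=float(s)) for l, m, s in zip(Ls, Ms, Ss)
    )
    return LMSCurve(
        measure_name=measure, ages=tuple(ages), points=points, smoothing_spec=spec
    )


# ---------------------------------------------------------------------------
# reporting

def percentile_table(
    curve: LMSCurve, alphas=DEFAULT_ALPHAS
) -> pd.DataFrame:
    """Age x percentile table of centile values; rows by age, columns by alpha."""
    specs = [PercentileSpec.from_alpha(float(al)) for al in alphas]
    cells = {}
    for spec in specs:
        col = []
        for age, pt in zip(curve.ages, curve.points):
            try:
                col.append(bccg_percentile(pt, spec))
            except ValueError as exc:
                raise ValueError(
                    f"infeasible centile at age {age}, alpha {spec.alpha}: {exc}"
                ) from exc
        cells[f"P{spec.alpha * 100:g}"] = col
    out = pd.DataFrame(cells, index=pd.Index(curve.ages, name="age"))
    return out


def decline_summary(series, units: str = "") -> DeclineSummary:
    """Mean and SD of year-on-year declines, plus overall percent change.

    ``series`` holds the values at consecutive integer ages (oldest last).
    Declines are v_i - v_{i+1}, so a falling series yields positive declines;
    overall_pct_change = 100 * (v_last - v_first) / v_first (negative when
    falling).  The SD uses the n-1 denominator and is 0 for a single step.
    """
    v = np.asarray(series, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 consecutive-age values")
    d = v[:-1] - v[1:]
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return DeclineSummary(
        mean_yearly_decline=float(np.mean(d)),
        sd_yearly_decline=sd,
        overall_pct_change=float(100.0 * (v[-1] - v[0]) / v[0]),
        n_steps=int(d.size),
    )
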