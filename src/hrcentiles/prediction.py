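"""MHR prediction equations and agreement analysis.

Ordinary least squares with forward/backward stepwise selection develops
age-based maximum-heart-rate equations; the fitted model is compared with
the classic Fox (220 - age) and Tanaka (208 - 0.7*age) equations through
Bland-Altman bias and 95 % limits of agreement.  Differences are always
measured - predicted, so an equation that predicts too low (underestimates)
yields a positive bias and one that predicts too high a negative bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionModel",
    "AgreementStats",
    "EQUATIONS",
    "fit_ols",
    "stepwise_select",
    "evaluate_equation",
    "bland_altman",
    "pearson_r",
    "group_compare",
]


@dataclass(frozen=True)
class RegressionModel:
    """An OLS fit: intercept-first coefficients with fit diagnostics.

    ``see`` is the standard error of the estimate sqrt(SSE / (n - p - 1))
    with p predictors; ``residual_range`` is (min, max) of in-sample
    residuals (response minus fitted).
    """

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first, then one per predictor
    r_squared: float
    see: float
    residual_range: tuple[float, float]
    n: int
    p_values: tuple[float, ...] = field(default=())  # aligned with coefficients

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    def predict(self, predictors: pd.DataFrame | dict) -> np.ndarray:
        X = pd.DataFrame(predictors)
        out = np.full(len(X), self.intercept, dtype=float)
        for name, coef in zip(self.predictor_names, self.coefficients[1:]):
            out += coef * X[name].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement: bias, SD of differences, 95 % limits."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


#: Named affine MHR equations: intercept, age slope, BMI slope (bpm units).
EQUATIONS: dict[str, tuple[float, float, float]] = {
    "model1": (225.08, -1.55, 0.0),
    "model2": (228.03, -1.45, -0.21),
    "fox": (220.0, -1.0, 0.0),
    "tanaka": (208.0, -0.7, 0.0),
}


def fit_ols(response, predictors: pd.DataFrame | dict) -> RegressionModel:
    """OLS of ``response`` on the named predictor columns (with intercept)."""
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    n, p = len(y), X.shape[1]
    if len(X) != n:
        raise ValueError("response and predictors must have equal length")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("degenerate response: zero total sum of squares")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    resid = fit.resid
    sse = float(np.sum(resid**2))
    return RegressionModel(
        predictor_names=tuple(X.columns),
        coefficients=tuple(float(c) for c in fit.params),
        r_squared=float(fit.rsquared),
        see=float(np.sqrt(sse / (n - p - 1))),
        residual_range=(float(resid.min()), float(resid.max())),
        n=n,
        p_values=tuple(float(v) for v in fit.pvalues),
    )


def stepwise_select(
    response,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[list[RegressionModel], list[str]]:
    """Forward-entry / backward-removal stepwise OLS by partial-F p-values.

    Returns the sequence of models after each successful entry (model 1,
    model 2, ...) and a human-readable selection trace.  An empty sequence
    (no candidate passes ``p_enter``) is a legitimate result, not an error.
    """
    if p_enter > p_remove:
        raise ValueError("require p_enter <= p_remove")
    y = np.asarray(response, dtype=float)
    cand = pd.DataFrame(candidates).astype(float)
    selected: list[str] = []
    models: list[RegressionModel] = []
    trace: list[str] = []

    def partial_f_p(base: list[str], extra: str) -> float:
        """p-value of the partial F test for adding ``extra`` to ``base``."""
        full = fit_ols(y, cand[base + [extra]])
        sse_full = full.see**2 * (full.n - len(base) - 2)
        if base:
            red = fit_ols(y, cand[base])
            sse_red = red.see**2 * (red.n - len(base) - 1)
        else:
            sse_red = float(np.sum((y - y.mean()) ** 2))
        df2 = full.n - len(base) - 2
        if sse_full <= 0:
            return 0.0
        f = (sse_red - sse_full) / (sse_full / df2)
        return float(stats.f.sf(f, 1, df2))

    while True:
        remaining = [c for c in cand.columns if c not in selected]
        if not remaining:
            break
        pvals = {c: partial_f_p(selected, c) for c in remaining}
        best = min(pvals, key=pvals.get)
        if pvals[best] >= p_enter:
            trace.append(f"stop: best remaining candidate {best} p={pvals[best]:.4g}")
            break
        selected.append(best)
        trace.append(f"enter {best} (p={pvals[best]:.4g})")
        # backward pass: drop any previously entered term whose partial p rose
        dropped = True
        while dropped and len(selected) > 1:
            dropped = False
            model = fit_ols(y, cand[selected])
            for name, pv in zip(model.predictor_names, model.p_values[1:]):
                if pv > p_remove:
                    selected.remove(name)
                    trace.append(f"remove {name} (p={pv:.4g})")
                    dropped = True
                    break
        models.append(fit_ols(y, cand[selected]))
    if not models:
        trace.append("empty model: no candidate passed p_enter")
    return models, trace


def evaluate_equation(
    equation: str | tuple[float, float, float],
    age,
    bmi=None,
) -> float | np.ndarray:
    """Predicted MHR from a named or custom affine equation.

    ``equation`` is one of ``model1 | model2 | fox | tanaka`` or a custom
    (intercept, age_slope, bmi_slope) triple; ``bmi`` is required iff the
    BMI slope is nonzero.
    """
    if isinstance(equation, str):
        try:
            coefs = EQUATIONS[equation]
        except KeyError:
            raise KeyError(
                f"unknown equation {equation!r}; choose from {sorted(EQUATIONS)}"
            ) from None
    else:
        coefs = tuple(equation)  # type: ignore[assignment]
    intercept, age_slope, bmi_slope = coefs
    age_a = np.asarray(age, dtype=float)
    if np.any(age_a <= 0):
        raise ValueError("age must be positive")
    out = intercept + age_slope * age_a
    if bmi_slope != 0.0:
        if bmi is None:
            raise ValueError("this equation requires bmi")
        out = out + bmi_slope * np.asarray(bmi, dtype=float)
    return float(out) if out.ndim == 0 else out


def bland_altman(measured, predicted) -> AgreementStats:
    """Bland-Altman agreement of predicted against measured values.

    differences = measured - predicted; bias is their mean, sd_diff the
    sample SD (n-1 denominator), and the limits bias +/- 1.96 * sd_diff.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size < 2:
        raise ValueError("need at least 2 paired values")
    d = m - p
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=int(m.size),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(xa, ya).statistic)


def group_compare(values, groups) -> dict:
    """One-way ANOVA across age groups plus Bonferroni-adjusted successive pairs.

    Consecutive age pairs are compared by two-sample t tests; each raw p is
    multiplied by the number of successive comparisons and capped at 1.
    Returns ``{"f": F, "p": p, "pairwise": {(a1, a2): p_adj, ...}}``.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[g == lev] for lev in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs >= 2 members")
    f_stat, p = stats.f_oneway(*samples)
    n_pairs = len(levels) - 1
    pairwise = {}
    for (a1, s1), (a2, s2) in zip(
        zip(levels[:-1], samples[:-1]), zip(levels[1:], samples[1:])
    ):
        raw = stats.ttest_ind(s1, s2).pvalue
        pairwise[(a1, a2)] = min(1.0, float(raw) * n_pairs)
    return {"f": float(f_stat), "p": float(p), "pairwise": pairwise}
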