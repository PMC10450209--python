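"""Box-Cox Cole-Green transform, per-group ML fit, LMS curves and declines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrcentiles.cohort import generate_bccg_sample
from hrcentiles.lms import (
    DEFAULT_ALPHAS,
    LMSCurve,
    LMSPoint,
    PercentileSpec,
    SmoothingSpec,
    bccg_loglik,
    bccg_percentile,
    bccg_zscore,
    decline_summary,
    fit_bccg_group,
    fit_lms_curve,
    percentile_table,
)

L_GRID = (-2.0, -1.0, -0.5, -1e-9, 0.5, 1.0, 2.0)
ALPHA_GRID = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)


class TestPercentileAndZscore:
    def test_median_is_m_for_any_l(self):
        for L in L_GRID:
            pt = LMSPoint(L=L, M=137.0, S=0.08)
            assert bccg_percentile(pt, 0.5) == pytest.approx(137.0, abs=1e-9)

    def test_affine_case_worked_example(self):
        pt = LMSPoint(L=1.0, M=100.0, S=0.05)
        assert bccg_percentile(pt, 0.975) == pytest.approx(109.80, abs=0.005)

    def test_small_l_matches_lognormal_limit(self):
        exact = bccg_percentile(LMSPoint(L=0.0, M=200.0, S=0.03), 0.97)
        near = bccg_percentile(LMSPoint(L=1e-8, M=200.0, S=0.03), 0.97)
        assert near == pytest.approx(exact, rel=1e-6)

    def test_zscore_trivial_cases(self):
        pt = LMSPoint(L=0.7, M=90.0, S=0.1)
        assert bccg_zscore(90.0, pt) == pytest.approx(0.0, abs=1e-12)
        pt1 = LMSPoint(L=1.0, M=90.0, S=0.1)
        assert bccg_zscore(90.0 * 1.1, pt1) == pytest.approx(1.0, abs=1e-12)

    def test_percentile_zscore_round_trip_over_grid(self):
        for L in L_GRID:
            for S in (0.03, 0.1):
                pt = LMSPoint(L=L, M=150.0, S=S)
                for alpha in ALPHA_GRID:
                    spec = PercentileSpec.from_alpha(alpha)
                    x = bccg_percentile(pt, spec)
                    assert bccg_zscore(x, pt) == pytest.approx(spec.z_alpha, abs=1e-9)

    def test_infeasible_tail_raises(self):
        # L=5, S=0.5: 1 + L*S*z < 0 at the 3rd percentile (z ~ -1.88)
        with pytest.raises(ValueError, match="infeasible"):
            bccg_percentile(LMSPoint(L=5.0, M=100.0, S=0.5), 0.03)

    def test_nonpositive_measurement_raises(self):
        with pytest.raises(ValueError):
            bccg_zscore(0.0, LMSPoint(L=1.0, M=100.0, S=0.05))


class TestFitBCCGGroup:
    def test_m_and_s_recovery_at_small_cv(self):
        # at S=0.03 the skewness signal is weak: L is estimable only on
        # average (SD(L-hat) ~ 0.8/(S*sqrt(n))), while M and S are sharp
        x = generate_bccg_sample(0.5, 200.0, 0.03, 10_000, seed=101)
        pt = fit_bccg_group(x)
        assert pt.M == pytest.approx(200.0, abs=1.0)
        assert pt.S == pytest.approx(0.03, abs=0.003)

    def test_l_recovery_averaged_over_seeds_at_small_cv(self):
        Ls = [
            fit_bccg_group(generate_bccg_sample(0.5, 200.0, 0.03, 10_000, seed=s)).L
            for s in range(300, 310)
        ]
        assert np.mean(Ls) == pytest.approx(0.5, abs=0.3)

    def test_full_recovery_where_l_is_well_identified(self):
        x = generate_bccg_sample(0.5, 200.0, 0.15, 10_000, seed=106)
        pt = fit_bccg_group(x)
        assert pt.L == pytest.approx(0.5, abs=0.15)
        assert pt.M == pytest.approx(200.0, abs=1.0)
        assert pt.S == pytest.approx(0.15, abs=0.005)

    def test_lognormal_data_recovers_l_near_zero(self):
        x = generate_bccg_sample(0.0, 120.0, 0.08, 10_000, seed=102)
        pt = fit_bccg_group(x)
        assert abs(pt.L) < 0.15

    def test_fit_beats_brute_force_likelihood_grid(self):
        x = generate_bccg_sample(0.8, 75.0, 0.06, 2000, seed=103)
        pt = fit_bccg_group(x)
        best = bccg_loglik(x, pt.L, pt.M, pt.S)
        grid_best = -np.inf
        for L in np.linspace(pt.L - 1.0, pt.L + 1.0, 21):
            for M in np.linspace(pt.M * 0.95, pt.M * 1.05, 21):
                for S in np.linspace(pt.S * 0.7, pt.S * 1.3, 21):
                    grid_best = max(grid_best, bccg_loglik(x, L, M, S))
        assert best >= grid_best - 1e-6

    def test_degenerate_and_small_inputs_raise(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_bccg_group(np.full(5, 10.0))
        with pytest.raises(ValueError, match="constant"):
            fit_bccg_group(np.full(50, 10.0))
        with pytest.raises(ValueError, match="positive"):
            fit_bccg_group(np.concatenate([np.full(30, 5.0), [-1.0]]))


class TestFitLMSCurve:
    def test_homogeneous_cohort_gives_flat_curve(self):
        rng_vals = generate_bccg_sample(1.0, 100.0, 0.05, 8 * 400, seed=104)
        df = pd.DataFrame({"age": np.repeat(np.arange(11, 19), 400), "x": rng_vals})
        curve = fit_lms_curve(df, "x")
        Ms = [p.M for p in curve.points]
        assert max(Ms) - min(Ms) < 1.5
        Ss = [p.S for p in curve.points]
        assert max(Ss) - min(Ss) < 0.01

    def test_anchored_cohort_recovers_endpoint_median(self, anchored_config):
        from hrcentiles.cohort import generate_cohort

        df = generate_cohort(anchored_config.model_copy(update={"n_players": 2400}))
        curve = fit_lms_curve(df, "mhr_bpm")
        assert curve.at(11).M == pytest.approx(208.64, abs=1.5)
        assert curve.at(18).M == pytest.approx(196.93, abs=1.5)

    def test_disabled_smoothing_keeps_per_age_estimates(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "age": np.repeat(np.arange(11, 15), 300),
                "x": np.concatenate(
                    [generate_bccg_sample(1.0, 100.0 + a, 0.05, 300, seed=200 + a)
                     for a in range(4)]
                ),
            }
        )
        no_smooth = SmoothingSpec(edf_L=None, edf_M=None, edf_S=None)
        curve = fit_lms_curve(df, "x", smoothing_spec=no_smooth)
        for age, pt in zip(curve.ages, curve.points):
            raw = fit_bccg_group(df.loc[df["age"] == age, "x"].to_numpy())
            assert pt.M == pytest.approx(raw.M, abs=1e-9)
            assert pt.L == pytest.approx(raw.L, abs=1e-9)

    def test_failing_group_names_the_age(self):
        df = pd.DataFrame({"age": np.repeat([11, 12], [300, 5]),
                           "x": np.abs(np.random.default_rng(0).normal(100, 5, 305))})
        with pytest.raises(RuntimeError, match="age 12"):
            fit_lms_curve(df, "x")


class TestPercentileTable:
    @pytest.fixture()
    def curve(self):
        ages = tuple(range(11, 19))
        points = tuple(
            LMSPoint(L=1.0 - 0.05 * i, M=208.64 - 1.673 * i, S=0.03)
            for i in range(8)
        )
        return LMSCurve(measure_name="mhr_bpm", ages=ages, points=points)

    def test_shape_and_median_column(self, curve):
        table = percentile_table(curve, DEFAULT_ALPHAS)
        assert table.shape == (8, 7)
        np.testing.assert_allclose(
            table["P50"].to_numpy(), [p.M for p in curve.points], atol=1e-9
        )

    def test_columns_strictly_increasing_in_alpha(self, curve):
        table = percentile_table(curve, DEFAULT_ALPHAS)
        vals = table.to_numpy()
        assert np.all(np.diff(vals, axis=1) > 0)

    def test_empirical_quantiles_match_table(self):
        pt = LMSPoint(L=0.4, M=180.0, S=0.05)
        x = generate_bccg_sample(pt.L, pt.M, pt.S, 100_000, seed=105)
        for alpha in (0.03, 0.5, 0.97):
            q = bccg_percentile(pt, alpha)
            dq = (bccg_percentile(pt, alpha + 5e-5) - bccg_percentile(pt, alpha - 5e-5)) / 1e-4
            se = np.sqrt(alpha * (1 - alpha) / x.size) * dq
            assert abs(np.quantile(x, alpha) - q) < 3 * se


class TestDeclineSummary:
    def test_published_endpoint_percent_change(self):
        ds = decline_summary([208.64, 196.93])
        assert round(ds.overall_pct_change, 2) == -5.61

    def test_constant_series(self):
        ds = decline_summary([70.0, 70.0, 70.0])
        assert ds.mean_yearly_decline == 0.0
        assert ds.sd_yearly_decline == 0.0
        assert ds.overall_pct_change == 0.0

    def test_linear_series_arithmetic(self):
        ds = decline_summary([10.0, 8.0, 6.0])
        assert ds.mean_yearly_decline == pytest.approx(2.0)
        assert ds.sd_yearly_decline == pytest.approx(0.0)
        assert ds.overall_pct_change == pytest.approx(-40.0)

    def test_sum_rule_mean_times_steps_equals_endpoint_difference(self):
        series = [208.64, 207.1, 205.0, 203.2, 201.4, 200.0, 198.1, 196.93]
        ds = decline_summary(series)
        assert ds.mean_yearly_decline * ds.n_steps == pytest.approx(
            series[0] - series[-1], abs=1e-9
        )

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            decline_summary([200.0])
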