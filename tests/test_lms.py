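"""BCCG transforms, density, sampling, and penalised-likelihood fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from vo2ref.cohort import generate_bccg
from vo2ref.equations import study_equation
from vo2ref.lms import (
    CentileTable,
    FitConfig,
    LmsCurveSet,
    LmsPoint,
    _SplineBasis,
    centile_table,
    fit_lms,
    lms_centile,
    lms_logdensity,
    lms_sample,
    lms_zscore,
)


class TestTransforms:
    @pytest.mark.parametrize("l", [-1.5, 0.0, 0.5, 1.0, 2.0])
    def test_median_maps_to_zero(self, l):
        assert lms_zscore(40.0, LmsPoint(l, 40.0, 0.12)) == pytest.approx(0.0, abs=1e-12)

    def test_l_equal_one_reduces_to_standardised_residual(self):
        p = LmsPoint(1.0, 40.0, 0.1)
        for y in (30.0, 40.0, 55.0):
            assert lms_zscore(y, p) == pytest.approx((y - 40.0) / 4.0, abs=1e-12)

    def test_continuity_across_the_log_switch(self):
        # tiny L agrees with the exact log-limit branch
        m, s = 40.0, 0.12
        for y in np.linspace(20.0, 80.0, 13):
            z0 = lms_zscore(y, LmsPoint(0.0, m, s))
            z_small = lms_zscore(y, LmsPoint(1e-9, m, s))
            z_above = lms_zscore(y, LmsPoint(2e-5, m, s))
            assert z_small == pytest.approx(z0, abs=1e-6)
            assert z_above == pytest.approx(z0, abs=1e-3)

    def test_z_zero_returns_median(self):
        assert lms_centile(0.0, LmsPoint(0.7, 38.0, 0.2)) == pytest.approx(38.0)

    def test_closed_form_centile(self):
        # M·(1 + L·S·z) at L = 1
        assert lms_centile(1.8808, LmsPoint(1.0, 40.0, 0.1)) == pytest.approx(47.52, abs=5e-3)

    @given(
        y=st.floats(10.0, 90.0),
        l=st.floats(-2.0, 2.0),
        m=st.floats(20.0, 60.0),
        s=st.floats(0.05, 0.3),
    )
    @settings(derandomize=True, max_examples=300)
    def test_round_trip_bijectivity(self, y, l, m, s):
        p = LmsPoint(l, m, s)
        back = lms_centile(lms_zscore(y, p), p)
        assert back == pytest.approx(y, rel=1e-10)

    def test_domain_errors(self):
        p = LmsPoint(1.0, 40.0, 0.2)
        with pytest.raises(ValueError):
            lms_zscore(-1.0, p)
        with pytest.raises(ValueError):
            lms_centile(-10.0, p)   # 1 + L·S·z <= 0


class TestDensity:
    def test_matches_gaussian_at_l_equal_one(self):
        m, s = 40.0, 0.05
        p = LmsPoint(1.0, m, s)
        for y in (35.0, 40.0, 44.0):
            expected = stats.norm.logpdf(y, loc=m, scale=m * s)
            assert lms_logdensity(y, p) == pytest.approx(expected, abs=1e-8)

    def test_integrates_to_one(self):
        p = LmsPoint(0.5, 40.0, 0.15)
        total, _ = quad(lambda y: np.exp(lms_logdensity(y, p)), 1e-9, 400.0, limit=300)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_mode_near_median_for_small_s(self):
        p = LmsPoint(0.5, 40.0, 0.03)
        ys = np.linspace(30.0, 50.0, 2001)
        dens = lms_logdensity(ys, p)
        assert abs(ys[np.argmax(dens)] - 40.0) < 0.5


class TestSampling:
    def test_seed_reproducibility(self):
        p = LmsPoint(1.0, 45.0, 0.18)
        assert np.array_equal(lms_sample(p, 100, seed=5), lms_sample(p, 100, seed=5))
        assert not np.array_equal(lms_sample(p, 100, seed=5), lms_sample(p, 100, seed=6))

    def test_sample_median_near_m(self):
        draws = lms_sample(LmsPoint(1.0, 45.0, 0.18), 100_000, seed=11)
        assert abs(np.median(draws) - 45.0) / 45.0 < 0.01

    def test_p3_tail_mass(self):
        p = LmsPoint(1.0, 45.0, 0.18)
        draws = lms_sample(p, 100_000, seed=11)
        p3 = lms_centile(-1.8808, p)
        assert np.mean(draws < p3) == pytest.approx(0.03, abs=0.005)


class TestFit:
    def test_constant_parameter_recovery_under_heavy_smoothing(self):
        ages, y = generate_bccg(LmsPoint(1.0, 45.0, 0.18), 2000, seed=42)
        cfg = FitConfig(lambda_l=np.inf, lambda_m=1e6, lambda_s=np.inf, l_init=1.0)
        curves = fit_lms(ages, y, cfg)
        _, m, s = curves.evaluate(curves.age_grid)
        assert np.all(np.abs(m - 45.0) / 45.0 < 0.02)
        assert np.all(np.abs(s - 0.18) / 0.18 < 0.15)

    def test_median_polynomial_recovery(self):
        eq = study_equation("male")
        curves_in = (
            lambda a: np.full_like(a, 1.0),
            lambda a: np.polyval(eq.coefficients, a),
            lambda a: np.full_like(a, 0.18),
        )
        ages, y = generate_bccg(curves_in, 2000, seed=7)
        fit = fit_lms(ages, y)
        grid = np.arange(10.0, 60.01, 0.5)
        _, m, _ = fit.evaluate(grid)
        truth = np.polyval(eq.coefficients, grid)
        assert np.max(np.abs(m - truth) / truth) < 0.03

    def test_infinite_penalty_collapses_l_to_constant(self):
        ages, y = generate_bccg(LmsPoint(1.0, 45.0, 0.18), 500, seed=5)
        curves = fit_lms(ages, y, FitConfig(lambda_l=np.inf, l_init=1.0))
        l, _, _ = curves.evaluate(curves.age_grid)
        assert l.max() - l.min() < 1e-3

    def test_penalized_loglik_monotone_over_iterations(self):
        ages, y = generate_bccg(LmsPoint(0.5, 40.0, 0.2), 800, seed=9)
        curves = fit_lms(ages, y, FitConfig(tol=1e-6, max_iter=30))
        assert np.all(np.diff(curves.loglik_trace) >= -1e-9)

    def test_fixed_l_constant_s_matches_penalized_spline_oracle(self, rng):
        # with L ≡ 1 and S constant the M-score is a weighted least-squares
        # residual, so the fit must agree with the closed-form ridge spline
        n = 1500
        ages = np.sort(6 + 59 * rng.random(n))
        truth = 45.0 - 0.15 * (ages - 30.0)
        s_true = 0.05
        y = truth * (1 + s_true * rng.standard_normal(n))
        lam_m = 50.0
        cfg = FitConfig(fix_l=1.0, lambda_s=np.inf, lambda_m=lam_m, tol=1e-8, max_iter=200)
        fit = fit_lms(ages, y, cfg)
        _, m_fit, s_fit = fit.evaluate(ages)
        basis = _SplineBasis(ages.min(), ages.max(), 8)
        B, P = basis.design(ages), basis.penalty()
        sigma2 = (np.mean(m_fit) * np.mean(s_fit)) ** 2
        oracle = B @ np.linalg.solve(B.T @ B + 2 * lam_m * sigma2 * P, B.T @ y)
        assert np.max(np.abs(m_fit - oracle) / oracle) < 0.005

    def test_degenerate_and_undersized_input_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_lms([20.0] * 10, [40.0] * 10)
        with pytest.raises(ValueError, match="distinct ages"):
            fit_lms([20.0] * 60, list(np.linspace(30, 50, 60)))

    def test_nonconvergence_is_flagged_not_raised(self):
        ages, y = generate_bccg(LmsPoint(1.0, 45.0, 0.18), 300, seed=3)
        curves = fit_lms(ages, y, FitConfig(max_iter=1, tol=1e-12))
        assert not curves.converged
        assert curves.n_iter == 1


@pytest.fixture(scope="module")
def fitted():
    ages, y = generate_bccg(LmsPoint(1.0, 45.0, 0.18), 1000, seed=21)
    return fit_lms(ages, y, FitConfig(lambda_l=np.inf, lambda_m=1e5, lambda_s=np.inf))


class TestCentileTable:
    def test_p50_equals_m(self, fitted):
        table = centile_table(fitted)
        _, m, _ = fitted.evaluate(table.age_grid)
        assert np.allclose(table.column(50.0), m, rtol=1e-12)

    def test_rows_strictly_increase_with_percentile(self, fitted):
        table = centile_table(fitted)
        assert np.all(np.diff(table.values, axis=1) > 0)

    def test_constant_curve_p97_closed_form(self):
        p = LmsPoint(1.0, 45.0, 0.18)
        z97 = stats.norm.ppf(0.97)
        assert z97 == pytest.approx(1.880794, abs=1e-6)
        assert lms_centile(z97, p) == pytest.approx(45 * (1 + 0.18 * 1.880794), abs=1e-3)

    def test_extrapolation_flagged(self, fitted):
        lo, hi = fitted.age_range
        table = centile_table(fitted, age_grid=[lo - 1.0, lo + 1.0, hi + 2.0])
        assert list(table.extrapolated) == [True, False, True]

    def test_percentiles_must_be_interior(self, fitted):
        with pytest.raises(ValueError):
            centile_table(fitted, percentiles=[0.0, 50.0])

    def test_csv_round_trip(self, fitted, tmp_path):
        table = centile_table(fitted)
        path = tmp_path / "centiles.csv"
        table.to_csv(path)
        back = CentileTable.from_csv(path)
        assert np.allclose(back.values, table.values)
        assert back.percentiles == table.percentiles

    def test_curve_set_csv_round_trip(self, fitted, tmp_path):
        path = tmp_path / "curves.csv"
        fitted.to_csv(path)
        import pandas as pd

        back = LmsCurveSet.from_frame(pd.read_csv(path))
        # exact at the exported grid; interpolation-accurate between knots
        for a, b in zip(back.evaluate(fitted.age_grid), fitted.evaluate(fitted.age_grid)):
            assert np.allclose(a, b, rtol=1e-12)
        mid = fitted.age_grid[:-1] + 0.25
        for a, b in zip(back.evaluate(mid), fitted.evaluate(mid)):
            assert np.allclose(a, b, rtol=1e-3)
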