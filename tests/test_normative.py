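"""SHASH normative model fitting, transfer, scoring and LR tests."""

import numpy as np
import pytest
from scipy.stats import kstest

from gradnorm.normative import (NormativeConfig, age_effect_test,
                                centile_scores, fit_normative,
                                normative_median_curve, sigma_age_test,
                                transfer_recalibrate)
from gradnorm.shash import shash_rvs

AGE_CFG = NormativeConfig(mu_terms=("age",))


def _ages(rng, n):
    return rng.uniform(5, 22, n)


@pytest.fixture(scope="module")
def sin_fit():
    rng = np.random.default_rng(1)
    age = _ages(rng, 1500)
    y = np.sin(age / 3) + rng.normal(0, 0.1, len(age))
    return fit_normative(y, age, None, AGE_CFG), age


class TestFit:
    def test_flat_gaussian_recovery(self):
        rng = np.random.default_rng(2)
        age = _ages(rng, 2000)
        y = rng.standard_normal(2000)
        m = fit_normative(y, age, None,
                          NormativeConfig(mu_terms=("age",),
                                          select_smoothing=True))
        grid = np.linspace(age.min(), age.max(), 60)
        mu = m.median(grid, None)
        assert np.abs(mu).max() < 0.1
        assert np.exp(m.theta_nu) < 0.2  # effectively zero skew on log link
        assert np.exp(m.theta_tau) == pytest.approx(1.0, abs=0.15)

    def test_smooth_mean_recovery(self, sin_fit):
        m, age = sin_fit
        lo, hi = np.quantile(age, [0.05, 0.95])
        grid = np.linspace(lo, hi, 120)
        rmse = np.sqrt(np.mean((m.median(grid, None) - np.sin(grid / 3)) ** 2))
        assert rmse < 0.05

    def test_sigma_trajectory_recovery(self):
        rng = np.random.default_rng(3)
        age = _ages(rng, 2000)
        y = rng.normal(0, np.exp(0.05 * age))
        m = fit_normative(y, age, None, AGE_CFG)
        _, s_lo, _, _ = m.predict_params(np.array([5.5]), None)
        _, s_hi, _, _ = m.predict_params(np.array([21.5]), None)
        slope = (np.log(s_hi[0]) - np.log(s_lo[0])) / 16.0
        assert slope == pytest.approx(0.05, rel=0.30)

    def test_input_validation(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="minimum"):
            fit_normative(rng.standard_normal(10), _ages(rng, 10), None, AGE_CFG)
        with pytest.raises(ValueError, match="constant"):
            fit_normative(rng.standard_normal(100), np.full(100, 9.0), None,
                          AGE_CFG)
        with pytest.raises(ValueError, match="sex"):
            fit_normative(rng.standard_normal(100), _ages(rng, 100), None,
                          NormativeConfig())

    def test_sex_interaction_changes_female_curve_only(self):
        rng = np.random.default_rng(5)
        age = _ages(rng, 1200)
        sex = rng.integers(0, 2, 1200)
        y = 0.05 * age * sex + rng.normal(0, 0.2, 1200)
        m = fit_normative(y, age, sex,
                          NormativeConfig(select_smoothing=True))
        grid = np.linspace(7, 20, 50)
        male = m.median(grid, np.zeros(50))
        female = m.median(grid, np.ones(50))
        assert np.abs(male).max() < 0.25
        assert np.mean(female - male) == pytest.approx(
            0.05 * grid.mean(), abs=0.15)


class TestTransfer:
    @pytest.fixture(scope="class")
    def base(self):
        rng = np.random.default_rng(6)
        age = _ages(rng, 1000)
        y = 0.3 * np.sin(age / 2.5) + rng.normal(0, 0.5, 1000)
        return fit_normative(y, age, None, AGE_CFG), y, age

    def test_self_transfer_is_fixed_point(self, base):
        m, y, age = base
        t = transfer_recalibrate(m, y, age)
        assert abs(t.meta["intercept_shift_mu"]) < 1e-3
        assert abs(t.meta["intercept_shift_logsigma"]) < 5e-3

    def test_location_shift_recovered(self, base):
        m, y, age = base
        t = transfer_recalibrate(m, y + 2.0, age)
        assert t.meta["intercept_shift_mu"] == pytest.approx(2.0, abs=0.02)

    def test_scale_shift_recovered(self, base):
        m, y, age = base
        y2 = (y - y.mean()) * 2.0 + y.mean()
        t = transfer_recalibrate(m, y2, age)
        assert t.meta["intercept_shift_logsigma"] == pytest.approx(
            np.log(2.0), abs=0.05)

    def test_empty_cohort_rejected(self, base):
        m, _, _ = base
        with pytest.raises(ValueError):
            transfer_recalibrate(m, [], [])


class TestScoring:
    def test_centiles_uniform_under_own_model(self, sin_fit):
        m, _ = sin_fit
        rng = np.random.default_rng(7)
        age = _ages(rng, 500)
        params = m.predict_params(age, None)
        y = shash_rvs(params, rng=rng)
        c = centile_scores(m, y, age, None)
        assert kstest(c, "uniform").statistic < 0.08

    def test_subject_on_median_curve_scores_one_half(self, sin_fit):
        m, _ = sin_fit
        age = np.array([8.0, 14.0, 20.0])
        y = m.median(age, None)
        c = centile_scores(m, y, age, None)
        np.testing.assert_allclose(c, 0.5, atol=1e-10)

    def test_extreme_values_clip_with_warning(self, sin_fit):
        m, _ = sin_fit
        with pytest.warns(UserWarning, match="clipped"):
            c = centile_scores(m, np.array([1e6]), np.array([10.0]), None)
        assert c[0] == pytest.approx(1 - 1e-6)

    def test_extrapolation_warns_not_errors(self, sin_fit):
        m, _ = sin_fit
        with pytest.warns(UserWarning, match="extrapolat"):
            centile_scores(m, np.array([0.0]), np.array([30.0]), None)

    def test_centiles_affine_equivariant(self):
        rng = np.random.default_rng(8)
        age = _ages(rng, 600)
        y = np.cos(age / 4) + rng.normal(0, 0.3, 600)
        cfg = AGE_CFG
        m1 = fit_normative(y, age, None, cfg)
        c1 = centile_scores(m1, y, age, None)
        m2 = fit_normative(3.0 * y - 5.0, age, None, cfg)
        c2 = centile_scores(m2, 3.0 * y - 5.0, age, None)
        np.testing.assert_allclose(c1, c2, atol=0.02)

    def test_median_curve_identities(self, sin_fit):
        m, _ = sin_fit
        grid = np.linspace(6, 21, 30)
        med = normative_median_curve(m, grid, None)
        from gradnorm.shash import shash_cdf

        params = m.predict_params(grid, None)
        np.testing.assert_allclose(shash_cdf(med, params), 0.5, atol=1e-10)

    def test_monotone_truth_gives_monotone_median(self):
        rng = np.random.default_rng(9)
        age = _ages(rng, 1200)
        y = 0.05 * age + rng.normal(0, 0.1, 1200)
        m = fit_normative(y, age, None, AGE_CFG)
        med = m.median(np.linspace(6, 21, 80), None)
        assert np.sum(np.diff(med) < -1e-4) <= 2  # monotone up to fit noise


class TestLikelihoodRatioTests:
    def test_planted_age_effect_detected(self):
        rng = np.random.default_rng(10)
        age = _ages(rng, 500)
        y = np.sin(age / 3) + rng.normal(0, 0.3, 500)
        res = age_effect_test(y, age, None, AGE_CFG)
        assert res.p < 1e-4

    def test_statistic_nonnegative_and_df_positive(self):
        rng = np.random.default_rng(11)
        age = _ages(rng, 400)
        y = rng.standard_normal(400)
        res = age_effect_test(y, age, None, AGE_CFG)
        assert res.statistic >= 0 and res.df > 0

    def test_sigma_trend_detected_with_sign(self):
        rng = np.random.default_rng(12)
        age = _ages(rng, 500)
        y = rng.normal(0, 1.5 * np.exp(-0.04 * age))
        res = sigma_age_test(y, age, None, AGE_CFG)
        assert res.p < 0.05
        assert res.sign == -1

    def test_sigma_statistic_grows_with_effect_size(self):
        rng = np.random.default_rng(13)
        age = _ages(rng, 600)
        flat = sigma_age_test(rng.normal(0, 1, 600), age, None, AGE_CFG)
        shrink = sigma_age_test(rng.normal(0, 2 * np.exp(-0.08 * age)),
                                age, None, AGE_CFG)
        assert shrink.statistic > flat.statistic

    def test_non_nested_structure_rejected(self):
        rng = np.random.default_rng(14)
        age = _ages(rng, 200)
        y = rng.standard_normal(200)
        with pytest.raises(ValueError):
            age_effect_test(y, age, None, NormativeConfig(mu_terms=()))


def test_gaic_smoothing_selection_runs_and_picks_grid_value():
    rng = np.random.default_rng(15)
    age = rng.uniform(5, 22, 400)
    y = np.sin(age / 3) + rng.normal(0, 0.2, 400)
    cfg = NormativeConfig(mu_terms=("age",), select_smoothing=True)
    m = fit_normative(y, age, None, cfg)
    assert m.meta["lam_mu"] in cfg.smoothing_grid
    assert "gaic" in m.meta
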