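"""Double-logistic model: analytic derivatives against finite differences,
parameter recovery, smoothing-spline limits, and phenophase geometry."""

import numpy as np
import pytest

import canopyphen as cp
from canopyphen.phenology import (DoubleLogisticModel, FitError, PhenoDates,
                                  curvature, curvature_change_rate,
                                  extract_phenophases, fit_double_logistic,
                                  signed_curvature, smooth_series)


class TestEvaluateModel:
    def test_saturates_to_minimum_on_both_sides(self, gei_params):
        assert cp.evaluate_model(gei_params, -1e4) == pytest.approx(8.0, abs=1e-9)
        assert cp.evaluate_model(gei_params, 1e4) == pytest.approx(8.0, abs=1e-9)

    def test_half_amplitude_at_spring_inflection(self, gei_params):
        # autumn sigmoid fully saturated at t = S (A - S >> 1/mA)
        expected = 8.0 + (45.0 - 8.0) / 2
        assert cp.evaluate_model(gei_params, 67.0) == pytest.approx(expected, abs=1e-6)

    def test_plateau_reaches_maximum(self, gei_params):
        assert cp.evaluate_model(gei_params, 200.0) == pytest.approx(45.0, abs=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(w_min=1.0, w_max=1.0), dict(s=200.0, a=100.0), dict(m_s=-0.1),
        dict(m_a=0.0)])
    def test_invalid_params_rejected(self, bad):
        kwargs = dict(w_min=0.0, w_max=1.0, s=67.0, a=337.0, m_s=0.1, m_a=0.1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            cp.DoubleLogisticParams(**kwargs)


class TestCurvature:
    def test_matches_finite_differences_of_g(self, gei_params):
        """Analytic curvature vs brute-force second differences of g."""
        t = np.linspace(30, 370, 1000)
        h = 1e-2
        g = lambda x: cp.evaluate_model(gei_params, x)
        g1 = (g(t + h) - g(t - h)) / (2 * h)
        g2 = (g(t + h) - 2 * g(t) + g(t - h)) / h**2
        k_fd = np.abs(g2) / (1 + g1**2) ** 1.5
        k = curvature(gei_params, t)
        assert np.max(np.abs(k_fd - k)) / k.max() < 1e-6

    def test_nonnegative_everywhere(self, gei_params):
        t = np.linspace(-50, 450, 2000)
        assert np.all(curvature(gei_params, t) >= 0)

    def test_zero_on_plateau(self, gei_params):
        # mid-plateau, both sigmoids saturated: g'' ~ amplitude * exp(-mS*dt)
        peak = curvature(gei_params, np.linspace(30, 100, 500)).max()
        assert curvature(gei_params, 200.0) < 1e-5 * peak
        assert abs(curvature_change_rate(gei_params, 200.0)) < 1e-5 * peak

    def test_rate_matches_finite_differences_of_curvature(self, gei_params):
        t = np.linspace(30, 370, 500)
        h = 1e-4
        fd_signed = (signed_curvature(gei_params, t + h)
                     - signed_curvature(gei_params, t - h)) / (2 * h)
        an = curvature_change_rate(gei_params, t)
        scale = np.max(np.abs(an))
        assert np.max(np.abs(fd_signed - an)) / scale < 1e-6
        fd_unsigned = (curvature(gei_params, t + h)
                       - curvature(gei_params, t - h)) / (2 * h)
        an_u = curvature_change_rate(gei_params, t, on_unsigned=True)
        assert np.max(np.abs(fd_unsigned - an_u)) / scale < 1e-6

    def test_unsigned_rate_antisymmetric_for_single_logistic(self):
        # push the autumn transition far away: the spring side is a lone sigmoid
        p = cp.DoubleLogisticParams(0.0, 1.0, 100.0, 5000.0, 0.12, 0.12)
        delta = np.linspace(0.5, 30, 40)
        left = curvature_change_rate(p, 100.0 - delta, on_unsigned=True)
        right = curvature_change_rate(p, 100.0 + delta, on_unsigned=True)
        np.testing.assert_allclose(right, -left, atol=1e-12)


class TestFit:
    def test_noiseless_self_consistency(self, gei_params):
        spec = cp.TrajectorySpec(gei_params, 1, 365, 0.0, 0)
        series = cp.generate_trajectory(spec)
        params, diag = fit_double_logistic(series)
        for name in ("w_min", "w_max", "s", "a", "m_s", "m_a"):
            assert getattr(params, name) == pytest.approx(
                getattr(gei_params, name), rel=1e-4)
        assert diag.rmse < 1e-6
        assert diag.r_squared > 0.999999

    def test_noisy_recovery_single_seed(self, gei_params):
        amp = gei_params.w_max - gei_params.w_min
        spec = cp.TrajectorySpec(gei_params, 1, 365, 0.02 * amp, seed=11)
        series = cp.generate_trajectory(spec)
        params, diag = fit_double_logistic(series)
        assert abs(params.s - gei_params.s) <= 2
        assert abs(params.a - gei_params.a) <= 2
        assert diag.r_squared > 0.99

    def test_flat_series_raises_fit_error(self):
        with pytest.raises(FitError, match="flat"):
            fit_double_logistic((np.arange(1, 51), np.full(50, 3.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            DoubleLogisticModel().fit([1, 2, 3], [0.1, 0.5, 0.1])

    def test_gappy_grid_accepted(self, gei_params):
        spec = cp.TrajectorySpec(gei_params, 1, 365, 0.0, 0)
        series = cp.generate_trajectory(spec)
        keep = np.ones(365, dtype=bool)
        keep[100:130] = False  # a month-long hole
        params, _ = fit_double_logistic((series.doys[keep], series.values[keep]))
        assert params.s == pytest.approx(gei_params.s, abs=0.5)

    def test_sklearn_interface(self, gei_params):
        spec = cp.TrajectorySpec(gei_params, 1, 365, 0.0, 0)
        s = cp.generate_trajectory(spec)
        model = DoubleLogisticModel().fit(s.doys, s.values)
        assert model.score(s.doys, s.values) > 0.999999
        assert model.get_params()["n_restarts"] == 5
        pred = model.predict([200.0])
        assert pred[0] == pytest.approx(45.0, abs=1e-3)


class TestSmoothing:
    def test_p_one_interpolates(self):
        rng = np.random.default_rng(0)
        t = np.arange(1, 21, dtype=float)
        y = rng.normal(size=20)
        np.testing.assert_allclose(smooth_series(t, y, 1.0), y, atol=1e-8)

    def test_small_p_approaches_line(self):
        rng = np.random.default_rng(1)
        t = np.arange(1, 41, dtype=float)
        y = 2.0 * t + rng.normal(0, 1, 40)
        smoothed = smooth_series(t, y, 1e-9)
        line = np.polyval(np.polyfit(t, y, 1), t)
        np.testing.assert_allclose(smoothed, line, atol=1e-3)

    def test_smoothing_reduces_error_to_truth(self, gei_params):
        spec = cp.TrajectorySpec(gei_params, 1, 365, 1.5, seed=2)
        series = cp.generate_trajectory(spec)
        truth = spec.truth()
        sm = smooth_series(series.doys.astype(float), series.values, 0.032)
        raw_rmse = np.sqrt(np.mean((series.values - truth) ** 2))
        sm_rmse = np.sqrt(np.mean((sm - truth) ** 2))
        assert sm_rmse < raw_rmse

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.arange(10.0), np.arange(10.0), 0.0)
        with pytest.raises(ValueError):
            smooth_series(np.arange(10.0), np.arange(10.0), 1.5)


class TestPhenophases:
    def test_extrema_bracket_inflections(self, gei_params):
        d = extract_phenophases(gei_params)
        assert d.sos < gei_params.s < d.moe
        assert d.cos < gei_params.a < d.eos
        assert d.sos < d.moe <= d.cos < d.eos

    def test_stable_under_grid_refinement(self, gei_params):
        coarse = extract_phenophases(gei_params, step=1.0)
        fine = extract_phenophases(gei_params, step=0.1)
        for k in ("sos", "moe", "cos", "eos"):
            assert abs(getattr(coarse, k) - getattr(fine, k)) <= 1

    def test_los_identity(self, gei_params):
        d = extract_phenophases(gei_params)
        assert d.los == d.moe - d.sos

    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            PhenoDates(sos=100, moe=90, cos=200, eos=300)

    def test_dates_converge_to_truth_as_noise_vanishes(self, gei_params):
        truth = extract_phenophases(gei_params)
        amp = gei_params.w_max - gei_params.w_min
        spec = cp.TrajectorySpec(gei_params, 1, 365, 0.001 * amp, seed=4)
        series = cp.generate_trajectory(spec)
        model = DoubleLogisticModel().fit(series.doys, series.values)
        fitted = model.transition_dates()
        for k in ("sos", "moe", "cos", "eos"):
            assert abs(getattr(fitted, k) - getattr(truth, k)) <= 1
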