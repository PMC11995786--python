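"""Delta-change scalers, their interpolation and application."""

import numpy as np
import pytest

import peatclim as pc


def _series(values, kind="temp_mean_c"):
    return pc.SubAnnualSeries(np.asarray(values, dtype=float), kind)


class TestClimatology:
    def test_single_year_identity(self):
        vals = np.arange(12.0)[None, :]
        assert np.array_equal(pc.interval_climatology(_series(vals)), vals[0])

    def test_two_year_mean(self):
        vals = np.array([[4.0] * 12, [6.0] * 12])
        assert np.allclose(pc.interval_climatology(_series(vals)), 5.0)

    def test_matches_bruteforce_column_means(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2.0, 30.0, size=(100, 12))
        expected = np.array([vals[:, j].sum() / 100 for j in range(12)])  # brute force
        got = pc.interval_climatology(_series(vals, "precip_total_mm"))
        assert np.allclose(got, expected, atol=1e-12)


class TestScalerComputation:
    def test_identical_climatologies_zero(self):
        base = np.array([5.0, 10.0])
        assert np.allclose(pc.temp_scalers(base, base), 0.0)
        assert np.allclose(pc.precip_scalers(base, base), 0.0)

    def test_temperature_signed_difference(self):
        assert np.allclose(pc.temp_scalers([5.0, 10.0], [6.0, 12.0]), [1.0, 2.0])
        assert np.allclose(pc.temp_scalers([10.0], [8.0]), [-2.0])  # cooling stays signed

    def test_precipitation_relative_difference(self):
        assert np.allclose(pc.precip_scalers([100.0], [90.0]), [-0.10])
        assert np.allclose(pc.precip_scalers([50.0], [75.0]), [0.50])

    def test_zero_baseline_rejected(self):
        with pytest.raises(pc.ValidationError, match="interval 2"):
            pc.precip_scalers([10.0, 0.0], [10.0, 5.0])

    def test_shape_mismatch(self):
        with pytest.raises(pc.ShapeError):
            pc.temp_scalers([1.0], [1.0, 2.0])


def _ramp_sets(dt_final, dp_final, n=12, periods=7):
    return pc.make_synthetic_scalers(np.full(n, dt_final), np.full(n, dp_final), periods)


class TestInterpolation:
    def test_zero_scalers_zero_trajectory(self):
        sets = pc.make_synthetic_scalers(np.zeros(12), np.zeros(12), n_periods=1)
        traj = pc.interpolate_scalers(sets, 100)
        assert np.all(traj.dtemp_c == 0.0)
        assert np.all(traj.dprecip_rel == 0.0)

    def test_knot_years_reproduce_scaler_values(self):
        # anchors placed on integer projection years are reproduced exactly
        sets = [
            pc.ScalerSet((2015, 2025), np.array([1.0]), np.array([0.1])),
            pc.ScalerSet((2035, 2045), np.array([3.0]), np.array([0.3])),
        ]
        traj = pc.interpolate_scalers(sets, 60)
        assert traj.dtemp_c[20 - 1, 0] == pytest.approx(1.0, abs=1e-9)
        assert traj.dtemp_c[40 - 1, 0] == pytest.approx(3.0, abs=1e-9)

    def test_linear_knots_reproduce_line(self):
        # knots collinear in anchor-year space (including the zero anchor)
        slope = 4.0 / 90.5
        sets = pc.make_synthetic_scalers(np.full(12, 1.0), np.zeros(12), 7)
        for s in sets:
            s.dtemp_c = np.full(12, slope * (s.anchor_year - 2000.0))
        traj = pc.interpolate_scalers(sets, 100)
        years = np.arange(1.0, 101.0)
        expected = np.minimum(years, 90.5) * slope
        assert np.max(np.abs(traj.dtemp_c[:, 0] - expected)) < 1e-9

    def test_held_constant_beyond_last_anchor(self):
        sets = _ramp_sets(4.0, -0.1)
        traj = pc.interpolate_scalers(sets, 100)
        # last anchor is 2090.5; years 91..100 hold the end state
        assert np.allclose(traj.dtemp_c[90:], 4.0, atol=1e-9)
        assert np.allclose(traj.dprecip_rel[90:], -0.1, atol=1e-9)

    def test_seasonality_preserved_per_interval(self):
        # perturbing one interval's knots must not move any other interval
        base = pc.make_synthetic_scalers(np.ones(12), np.zeros(12))
        pert = pc.make_synthetic_scalers(np.ones(12), np.zeros(12))
        for s in pert:
            s.dtemp_c = s.dtemp_c.copy()
            s.dtemp_c[4] += 2.0
        t0 = pc.interpolate_scalers(base, 100)
        t1 = pc.interpolate_scalers(pert, 100)
        others = [j for j in range(12) if j != 4]
        assert np.array_equal(t0.dtemp_c[:, others], t1.dtemp_c[:, others])
        assert not np.allclose(t0.dtemp_c[:, 4], t1.dtemp_c[:, 4])

    def test_overshoot_stays_above_minus_one(self):
        # a steep drop then recovery makes the cubic overshoot below -1
        sets = [
            pc.ScalerSet((2010, 2011), np.zeros(1), np.array([-0.999])),
            pc.ScalerSet((2012, 2013), np.zeros(1), np.array([-0.999])),
            pc.ScalerSet((2030, 2031), np.zeros(1), np.array([0.5])),
            pc.ScalerSet((2090, 2091), np.zeros(1), np.array([0.5])),
        ]
        traj = pc.interpolate_scalers(sets, 95)
        assert np.all(traj.dprecip_rel > -1.0)

    def test_empty_sets_rejected(self):
        with pytest.raises(pc.ValidationError):
            pc.interpolate_scalers([], 100)


class TestApplyScenario:
    def _tail(self, years=100, n=12):
        rng = np.random.default_rng(9)
        p = _series(rng.gamma(2.0, 40.0, (years, n)), "precip_total_mm")
        t = _series(rng.normal(8.0, 2.0, (years, n)), "temp_mean_c")
        return p, t

    def test_zero_trajectory_is_identity(self):
        p, t = self._tail()
        traj = pc.ScalerTrajectory(np.zeros((100, 12)), np.zeros((100, 12)))
        p2, t2 = pc.apply_scenario(p, t, traj)
        assert np.array_equal(p2.values, p.values)
        assert np.array_equal(t2.values, t.values)

    def test_constant_warming_additive(self):
        p, t = self._tail()
        traj = pc.ScalerTrajectory(np.full((100, 12), 2.0), np.zeros((100, 12)))
        _, t2 = pc.apply_scenario(p, t, traj)
        assert np.allclose(t2.values - t.values, 2.0)

    def test_halving_precipitation_multiplicative(self):
        p, t = self._tail()
        traj = pc.ScalerTrajectory(np.zeros((100, 12)), np.full((100, 12), -0.5))
        p2, _ = pc.apply_scenario(p, t, traj)
        assert np.allclose(p2.values, 0.5 * p.values)
        assert np.all(p2.values >= 0.0)

    def test_shape_mismatch_rejected(self):
        p, t = self._tail(years=50)
        traj = pc.ScalerTrajectory(np.zeros((100, 12)), np.zeros((100, 12)))
        with pytest.raises(pc.ShapeError):
            pc.apply_scenario(p, t, traj)


class TestScenarioModulator:
    def test_fit_transform_round_trip_null(self):
        mod = pc.ScenarioModulator(horizon_years=50)
        sets = pc.make_synthetic_scalers(np.zeros(12), np.zeros(12))
        rng = np.random.default_rng(1)
        p = _series(rng.gamma(2.0, 40.0, (50, 12)), "precip_total_mm")
        t = _series(rng.normal(8.0, 2.0, (50, 12)), "temp_mean_c")
        p2, t2 = mod.fit(sets).transform((p, t))
        assert np.array_equal(p2.values, p.values)
        assert np.array_equal(t2.values, t.values)

    def test_params_round_trip(self):
        mod = pc.ScenarioModulator(horizon_years=42)
        assert pc.ScenarioModulator(**mod.get_params()).horizon_years == 42
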