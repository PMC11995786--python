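"""Modified Thornthwaite potential evapotranspiration.

Derived expected values were frozen from high-precision sympy evaluations
of the same closed forms (see the oracle helpers at the bottom).
"""

import numpy as np
import pytest
import sympy as sp

import peatclim as pc


class TestHeatIndex:
    def test_constant_five_degrees_gives_twelve(self):
        # each (5/5)^1.514 term is 1; the 12/N factor makes I interval-invariant
        assert pc.heat_index(np.full(12, 5.0), 12) == pytest.approx(12.0)
        assert pc.heat_index(np.full(52, 5.0), 52) == pytest.approx(12.0)

    def test_constant_ten_degrees(self):
        # frozen oracle: 12 * 2**1.514 evaluated at 50 digits
        assert pc.heat_index(np.full(12, 10.0), 12) == pytest.approx(
            34.272095512441539674, rel=1e-12
        )

    def test_negative_temperatures_contribute_nothing(self):
        t = np.full(12, 8.0)
        t[[0, 1, 11]] = -10.0
        assert pc.heat_index(t, 12) == pytest.approx(pc.heat_index(np.maximum(t, 0.0), 12))

    def test_interval_invariance_of_constant_year(self):
        for t in (2.0, 9.3, 17.0):
            assert pc.heat_index(np.full(52, t), 52) == pytest.approx(
                pc.heat_index(np.full(12, t), 12), rel=1e-12
            )


class TestExponent:
    @pytest.mark.parametrize(
        "heat_idx,expected",
        [
            (0.0, 0.49239),  # the polynomial's constant term
            (100.0, 2.18839),  # 0.675 - 0.771 + 1.792 + 0.49239
            (34.272095512441539674, 1.0431583604164400578),  # frozen sympy oracle
        ],
    )
    def test_polynomial_values(self, heat_idx, expected):
        assert pc.exponent_a(heat_idx) == pytest.approx(expected, rel=1e-12)


class TestPetUnscaled:
    def test_freezing_gives_zero(self):
        assert pc.pet_unscaled(0.0, 34.0, 1.04) == 0.0
        assert pc.pet_unscaled(-7.5, 34.0, 1.04) == 0.0

    def test_reference_point_sixteen(self):
        # when 10 t = I the power base is 1, so PET = 16 regardless of a
        assert pc.pet_unscaled(3.4, 34.0, 1.2345) == pytest.approx(16.0)

    def test_frozen_oracle_value(self):
        i = 34.272095512441539674
        assert pc.pet_unscaled(10.0, i, pc.exponent_a(i)) == pytest.approx(
            48.893431868564658333, rel=1e-12
        )


class TestSolarGeometry:
    def test_declination_zero_at_j81(self):
        assert pc.solar_declination(81) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("j,expected", [(172, 23.449782846813658716),
                                            (355, -23.449782846813658716)])
    def test_declination_solstices(self, j, expected):
        assert pc.solar_declination(j) == pytest.approx(expected, rel=1e-12)

    def test_twelve_hours_at_zero_declination(self):
        for lat in (-60.0, 0.0, 58.288):
            assert pc.day_length(lat, 0.0) == pytest.approx(12.0)

    def test_twelve_hours_at_equator(self):
        for dec in (-23.45, -5.0, 11.0, 23.45):
            assert pc.day_length(0.0, dec) == pytest.approx(12.0)

    def test_wick_winter_day_length(self):
        # frozen sympy oracle at lat 58.454, delta -23.45
        assert pc.day_length(58.454, -23.45) == pytest.approx(6.0056601917723459804, rel=1e-12)

    def test_polar_clamping(self):
        assert pc.day_length(85.0, 23.45) == pytest.approx(24.0)
        assert pc.day_length(85.0, -23.45) == pytest.approx(0.0)


class TestScalePet:
    def test_reference_interval_unchanged(self):
        assert pc.scale_pet(48.9, 12.0, 30) == pytest.approx(48.9)

    def test_half_daylight_halves(self):
        assert pc.scale_pet(48.9, 6.0, 30) == pytest.approx(24.45)

    def test_weekly_interval(self):
        assert pc.scale_pet(48.9, 12.0, 7) == pytest.approx(11.41)


class TestPetSeries:
    def test_freezing_year_is_all_zero(self, site, calendar12):
        temp = pc.SubAnnualSeries(np.full((1, 12), -3.0), "temp_mean_c")
        out = pc.pet_series(temp, site, calendar12)
        assert np.all(out.values == 0.0)

    def test_constant_ten_degrees_at_equator(self, calendar12):
        equator = pc.SiteMeta("equator", lat=0.0, lon=0.0)
        temp = pc.SubAnnualSeries(np.full((1, 12), 10.0), "temp_mean_c")
        out = pc.pet_series(temp, equator, calendar12)
        expected = 48.893431868564658333 * calendar12.day_counts / 30.0
        assert np.allclose(out.values[0], expected, rtol=1e-10)

    def test_warming_never_decreases_annual_pet(self, site, calendar12):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            t = rng.uniform(0.0, 30.0, size=(1, 12))
            base = pc.pet_series(pc.SubAnnualSeries(t, "temp_mean_c"), site, calendar12)
            warm = pc.pet_series(pc.SubAnnualSeries(t + 1.0, "temp_mean_c"), site, calendar12)
            assert warm.values.sum() >= base.values.sum() - 1e-9

    def test_nonnegative_and_zero_below_freezing(self, site, calendar12):
        rng = np.random.default_rng(5)
        t = rng.uniform(-10.0, 25.0, size=(30, 12))
        out = pc.pet_series(pc.SubAnnualSeries(t, "temp_mean_c"), site, calendar12)
        assert np.all(out.values >= 0.0)
        assert np.all(out.values[t <= 0.0] == 0.0)

    def test_weekly_series_shape(self, site, calendar52):
        t = np.clip(8.5 - 5.5 * np.cos(2 * np.pi * np.arange(52) / 52), 0, None)
        out = pc.pet_series(
            pc.SubAnnualSeries(np.tile(t, (3, 1)), "temp_mean_c"), site, calendar52
        )
        assert out.values.shape == (3, 52)


class TestNetRainfall:
    def test_zero_pet_returns_precip(self):
        p = pc.SubAnnualSeries(np.full((2, 12), 50.0), "precip_total_mm")
        z = pc.SubAnnualSeries(np.zeros((2, 12)), "pet_mm")
        assert np.array_equal(pc.net_rainfall(p, z).values, p.values)

    def test_negative_net_allowed(self):
        p = pc.SubAnnualSeries([[50.0]], "precip_total_mm")
        e = pc.SubAnnualSeries([[60.0]], "pet_mm")
        assert pc.net_rainfall(p, e).values[0, 0] == pytest.approx(-10.0)

    def test_shape_mismatch_rejected(self):
        p = pc.SubAnnualSeries(np.zeros((2, 12)), "precip_total_mm")
        e = pc.SubAnnualSeries(np.zeros((3, 12)), "pet_mm")
        with pytest.raises(pc.ShapeError):
            pc.net_rainfall(p, e)


# --------------------------------------------------------------- sympy oracle
def oracle_heat_index(temps, n):
    acc = sp.Float(0, 40)
    for t in temps:
        if t > 0:
            acc += (sp.Float(repr(float(t)), 40) / 5) ** sp.Float("1.514", 40)
    return acc * sp.Rational(12, int(n))


def oracle_exponent(i):
    i = sp.Float(repr(float(i)), 40)
    return (
        sp.Float("675e-9", 40) * i**3
        - sp.Float("771e-7", 40) * i**2
        + sp.Float("1792e-5", 40) * i
        + sp.Float("0.49239", 40)
    )


def oracle_day_length(lat, dec):
    lat = sp.Float(repr(float(lat)), 40) * sp.pi / 180
    dec = sp.Float(repr(float(dec)), 40) * sp.pi / 180
    arg = -sp.tan(lat) * sp.tan(dec)
    arg = sp.Max(sp.Integer(-1), sp.Min(sp.Integer(1), arg))
    return (24 / sp.pi) * sp.acos(arg)


def oracle_scale_pet(pet, hours, days):
    return (
        sp.Float(repr(float(pet)), 40)
        * sp.Float(repr(float(hours)), 40) / 12
        * sp.Rational(int(days), 30)
    )


class TestOracleAgreement:
    """Spot agreement with the independent high-precision evaluations (the
    exhaustive 1000-input sweep lives in the acceptance suite)."""

    def test_heat_index_random_years(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.choice([12, 52]))
            t = rng.uniform(-5.0, 30.0, size=n)
            expected = float(sp.N(oracle_heat_index(t, n), 30))
            assert pc.heat_index(t, n) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_day_length_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            lat = float(rng.uniform(-89.0, 89.0))
            dec = float(rng.uniform(-23.45, 23.45))
            expected = float(sp.N(oracle_day_length(lat, dec), 30))
            assert pc.day_length(lat, dec) == pytest.approx(expected, rel=1e-9, abs=1e-12)
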