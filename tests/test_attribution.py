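import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvocanom.attribution import (
    AnomalySeries,
    ErrorBudget,
    anomaly_series,
    combine_contributions,
    contributions_for_year,
    interaction_term,
    moving_average,
    piecewise_slopes,
    propagate_errors,
)
from bvocanom.drivers import ContributionSet, ResponseParams
from conftest import END_YEAR, REF_YEAR, linear_series, prescribed_drivers


class TestInteraction:
    def test_printed_cross_term(self):
        # the unique value making the printed parts sum to the printed net
        assert interaction_term(0.24, (0.207, 0.085, -0.0528)) == pytest.approx(0.0574, abs=5e-5)

    def test_zero_biomass(self):
        assert interaction_term(0.0, (0.2, 0.1, -0.05)) == 0.0

    def test_zero_env_sum(self):
        assert interaction_term(0.24, (0.1, -0.06, -0.04)) == pytest.approx(0.0, abs=1e-15)

    def test_mapping_input(self):
        assert interaction_term(0.5, {"t": 0.2, "c": 0.1}) == pytest.approx(0.15)


class TestCombine:
    def test_printed_net_anomaly(self, printed_contributions):
        net = combine_contributions(printed_contributions, include_interaction=True)
        assert net == pytest.approx(0.5366, abs=5e-5)

    def test_all_zero(self):
        c = ContributionSet({"total": 0.0}, 0.0, 0.0, 0.0)
        assert combine_contributions(c) == 0.0

    def test_plain_sum_without_interaction(self, printed_contributions):
        net = combine_contributions(printed_contributions, include_interaction=False)
        assert net == pytest.approx(0.4792, abs=5e-5)

    @settings(max_examples=50)
    @given(
        b=st.floats(-0.3, 0.5), t=st.floats(-0.3, 0.5),
        c=st.floats(-0.3, 0.5), s=st.floats(-0.3, 0.5),
    )
    def test_matches_multiplicative_first_order(self, b, t, c, s):
        # combined == (1+b)(1+e)-1 exactly, where e is the additive env sum
        cs = ContributionSet({"total": b}, t, c, s)
        env = t + c + s
        expected = (1 + b) * (1 + env) - 1
        assert combine_contributions(cs) == pytest.approx(expected, abs=abs(b * env) * 1e-12 + 1e-12)


class TestPropagateErrors:
    def test_linear_sum_default(self, printed_contributions):
        half = propagate_errors(printed_contributions, ErrorBudget())
        assert half == pytest.approx(0.0357, abs=5e-5)

    def test_zero_margins(self, printed_contributions):
        zero = ErrorBudget(margins={k: 0.0 for k in ("biomass", "temperature", "soil_moisture", "co2")})
        assert propagate_errors(printed_contributions, zero) == 0.0

    def test_quadrature(self, printed_contributions):
        half = propagate_errors(printed_contributions, method="quadrature")
        assert half == pytest.approx(0.0202, abs=5e-5)

    def test_unknown_method_rejected(self, printed_contributions):
        with pytest.raises(ValueError, match="method"):
            propagate_errors(printed_contributions, method="bootstrap")
        with pytest.raises(ValueError, match="method"):
            ErrorBudget(method="bootstrap")

    def test_missing_margin_rejected(self, printed_contributions):
        with pytest.raises(ValueError, match="missing"):
            propagate_errors(printed_contributions, ErrorBudget(margins={"biomass": 0.03}))

    def test_interaction_term_widens_margin(self, printed_contributions):
        base = propagate_errors(printed_contributions)
        wider = propagate_errors(printed_contributions, include_interaction=True)
        assert wider > base


class TestAnomalySeries:
    def test_constant_drivers_give_zero_series(self, worked, params):
        d = prescribed_drivers(worked)
        flat = {
            "ndvi": {c: linear_series("NDVI", REF_YEAR, END_YEAR, 0.5, 0.5)
                     for c in d["ndvi"]},
            "temperature": linear_series("temperature", REF_YEAR, END_YEAR, 8.0, 8.0),
            "co2": linear_series("CO2", REF_YEAR, END_YEAR, 1.0, 1.0),
            "soil_moisture": linear_series("soil_moisture", REF_YEAR, END_YEAR, 0.3, 0.3),
        }
        series = anomaly_series(flat["ndvi"], flat["temperature"], flat["co2"],
                                flat["soil_moisture"], d["biomass_model"], params,
                                d["class_weights"], REF_YEAR)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_prescribed_endpoint(self, worked, params):
        d = prescribed_drivers(worked)
        series = anomaly_series(d["ndvi"], d["temperature"], d["co2"], d["soil_moisture"],
                                d["biomass_model"], params, d["class_weights"], REF_YEAR)
        assert series.value_at(REF_YEAR) == 0.0
        assert series.value_at(END_YEAR) == pytest.approx(0.5366, abs=0.002)

    def test_zero_noise_recovery_exact(self, worked, params):
        # each driver's recovered contribution matches its prescription
        d = prescribed_drivers(worked)
        c = contributions_for_year(END_YEAR, d["ndvi"], d["temperature"], d["co2"],
                                   d["soil_moisture"], d["biomass_model"], params,
                                   d["class_weights"], REF_YEAR)
        w = worked["contributions"]
        for cls, part in w["biomass_parts"].items():
            assert c.biomass_parts[cls] == pytest.approx(part, abs=1e-6)
        assert c.temperature == pytest.approx(np.expm1(0.1 * worked["temperature_trend_c"]), abs=1e-9)
        assert c.co2 == pytest.approx((worked["co2_ratio"] ** -0.33 - 1) * 0.5, abs=1e-9)
        assert c.soil_moisture == pytest.approx(worked["soil_moisture_relative_anomaly"], abs=1e-9)

    def test_rereference_to_endpoint(self, worked, params):
        d = prescribed_drivers(worked)
        series = anomaly_series(d["ndvi"], d["temperature"], d["co2"], d["soil_moisture"],
                                d["biomass_model"], params, d["class_weights"], REF_YEAR)
        shifted = series.rereference(END_YEAR)
        assert shifted.value_at(END_YEAR) == 0.0
        expected = (1 + series.values) / (1 + series.value_at(END_YEAR)) - 1
        np.testing.assert_allclose(shifted.values, expected, atol=1e-14)
        # recomputing against the new reference agrees to first order
        recomputed = anomaly_series(d["ndvi"], d["temperature"], d["co2"],
                                    d["soil_moisture"], d["biomass_model"], params,
                                    d["class_weights"], END_YEAR)
        np.testing.assert_allclose(recomputed.values, shifted.values, atol=8e-3)

    def test_reference_outside_span_rejected(self, worked, params):
        d = prescribed_drivers(worked)
        with pytest.raises(ValueError, match="reference year"):
            anomaly_series(d["ndvi"], d["temperature"], d["co2"], d["soil_moisture"],
                           d["biomass_model"], params, d["class_weights"], 1900)

    def test_short_driver_rejected_by_name(self, worked, params):
        d = prescribed_drivers(worked)
        short_t = linear_series("temperature", REF_YEAR + 5, END_YEAR, 8.2, 9.88)
        with pytest.raises(ValueError, match="temperature"):
            anomaly_series(d["ndvi"], short_t, d["co2"], d["soil_moisture"],
                           d["biomass_model"], params, d["class_weights"], REF_YEAR)

    def test_monte_carlo_recovery_with_noise(self, worked, params):
        # noisy drivers: mean endpoint over seeds stays near the prescription
        noise = {"temperature": 0.3, "NDVI": 0.01, "soil_moisture": 0.002}
        endpoints = []
        for seed in range(100):
            d = prescribed_drivers(worked, noise=noise, seed=seed)
            c = contributions_for_year(END_YEAR, d["ndvi"], d["temperature"], d["co2"],
                                       d["soil_moisture"], d["biomass_model"], params,
                                       d["class_weights"], REF_YEAR)
            endpoints.append(combine_contributions(c))
        truth = 0.53744  # deterministic endpoint of the prescribed drivers
        assert np.mean(endpoints) == pytest.approx(truth, abs=0.02)


class TestMovingAverage:
    def make(self, values, start=2000):
        years = np.arange(start, start + len(values))
        return AnomalySeries(years, np.asarray(values, dtype=float), start)

    def test_window_one_identity(self):
        s = self.make([0.0, 1.0, 4.0, 9.0])
        np.testing.assert_array_equal(moving_average(s, 1).values, s.values)

    def test_constant_unchanged(self):
        s = self.make([2.0] * 10)
        for w in (2, 3, 4, 7):
            np.testing.assert_allclose(moving_average(s, w).values, 2.0, atol=1e-15)

    def test_truncated_window_oracle(self):
        s = self.make([0.0, 1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(moving_average(s, 3).values, [0.5, 1, 2, 3, 3.5])

    def test_even_window(self):
        s = self.make([0.0, 1.0, 2.0, 3.0, 4.0])
        # window 4 spans i-1..i+2 truncated
        np.testing.assert_allclose(moving_average(s, 4).values,
                                   [1.0, 1.5, 2.5, 3.0, 3.5])

    def test_too_long_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            moving_average(self.make([0.0, 1.0]), 3)

    @settings(max_examples=30)
    @given(st.lists(st.floats(-1, 1), min_size=4, max_size=20),
           st.integers(1, 4), st.floats(-2, 2))
    def test_commutes_with_constant_shift(self, values, window, const):
        s = self.make(values)
        lhs = moving_average(self.make([v + const for v in values]), window).values
        rhs = moving_average(s, window).values + const
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestPiecewiseSlopes:
    def test_exact_line(self):
        years = np.arange(1987, 2006)
        s = AnomalySeries(years, 0.024 * (years - 1987), 1987)
        segs = piecewise_slopes(s, [])
        assert segs[0][2] == pytest.approx(2.4, abs=1e-9)

    def test_flat_series(self):
        years = np.arange(1979, 2025)
        s = AnomalySeries(years, np.zeros(years.size), 1979)
        for _, _, slope in piecewise_slopes(s, [1987, 2005]):
            assert slope == pytest.approx(0.0, abs=1e-12)

    def test_segment_recovery_under_noise(self):
        # regime slopes 2.4, 0.6, -1.2 %/yr with 0.3% noise
        years = np.arange(1979, 2025)
        # continuous piecewise-linear series over the three regimes
        true = {"a": 0.024, "b": 0.006, "c": -0.012}
        values = np.zeros(years.size, dtype=float)
        for i in range(1, years.size):
            y = years[i]
            slope = true["a"] if y <= 1987 else true["b"] if y <= 2005 else true["c"]
            values[i] = values[i - 1] + slope
        rng = np.random.default_rng(0)
        worst = {"a": 0.0, "b": 0.0, "c": 0.0}
        for seed in range(20):
            noisy = values + rng.normal(0, 0.003, values.size)
            s = AnomalySeries(years, noisy, 1979)
            segs = piecewise_slopes(s, [1987, 2005])
            for (lo, hi, slope), key in zip(segs, ("a", "b", "c")):
                worst[key] = max(worst[key], abs(slope - true[key] * 100))
        for key in true:
            assert worst[key] <= 0.15

    def test_small_segment_rejected(self):
        years = np.arange(2000, 2010)
        s = AnomalySeries(years, np.zeros(10), 2000)
        with pytest.raises(ValueError, match="fewer than 3"):
            piecewise_slopes(s, [2001])

    def test_breakpoint_outside_span_rejected(self):
        years = np.arange(2000, 2010)
        s = AnomalySeries(years, np.zeros(10), 2000)
        with pytest.raises(ValueError, match="outside"):
            piecewise_slopes(s, [1990])
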