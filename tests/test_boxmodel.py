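import numpy as np
import pytest
from hypothesis import given, strategies as st

import radonroom as rr
from radonroom.boxmodel import (BoxModelError, DoseParams, LAMBDA_RN_PER_H,
                                WellMixedParams, steady_concentration_table)

#: published analytical steady concentrations over the studied ACH range
SWEEP = {0.3: 221.60, 0.5: 138.22, 1.0: 74.59, 1.5: 53.17, 2.0: 42.42,
         4.3: 25.11}


class TestSteadyState:
    def test_calibrated_generation_reproduces_full_sweep(self):
        g = rr.calibrate_generation(SWEEP[0.3], 0.3, 10.0)
        for ach, expected in SWEEP.items():
            p = WellMixedParams(generation=g, ach=ach, outdoor=10.0)
            assert rr.wellmixed_steady(p) == pytest.approx(expected,
                                                           abs=0.01)

    def test_calibrated_generation_magnitude(self):
        g = rr.calibrate_generation(221.60, 0.3, 10.0)
        assert g == pytest.approx(65.1, abs=0.2)
        # ~11x the exhalation-derived generation rate of the same room
        g_exh = rr.generation_from_exhalation(
            {"all": 3.1}, {"all": 63.2}, 33.6)
        assert g / g_exh == pytest.approx(11.2, abs=0.3)

    def test_zero_source_zero_outdoor(self):
        p = WellMixedParams(generation=0.0, ach=1.0, outdoor=0.0)
        assert rr.wellmixed_steady(p) == 0.0

    def test_without_outdoor_inflow_matches_textbook_form(self):
        p = WellMixedParams(generation=65.0, ach=1.0, outdoor=10.0,
                            include_outdoor_inflow=False)
        assert rr.wellmixed_steady(p) == pytest.approx(
            65.0 / (1.0 + LAMBDA_RN_PER_H))

    @given(g=st.floats(1.0, 500.0), ach_lo=st.floats(0.1, 3.0),
           dach=st.floats(0.05, 2.0))
    def test_steady_decreasing_in_ventilation(self, g, ach_lo, dach):
        # holds whenever the source exceeds the outdoor-supported level
        c_lo = rr.wellmixed_steady(WellMixedParams(generation=g, ach=ach_lo,
                                                   outdoor=10.0))
        c_hi = rr.wellmixed_steady(WellMixedParams(generation=g,
                                                   ach=ach_lo + dach,
                                                   outdoor=10.0))
        if g > 10.0 * LAMBDA_RN_PER_H:
            assert c_hi < c_lo


class TestTimeseries:
    def test_starts_at_initial_value(self):
        p = WellMixedParams(generation=65.0, ach=1.0, initial=123.0)
        assert rr.wellmixed_timeseries(p, [0.0])[0] == pytest.approx(123.0)

    def test_five_time_constants_reach_steady_within_1pct(self):
        p = WellMixedParams(generation=65.0, ach=0.5, initial=0.0)
        t5 = 5.0 / p.lambda_total
        c = rr.wellmixed_timeseries(p, [t5])[0]
        assert abs(c - rr.wellmixed_steady(p)) / rr.wellmixed_steady(p) < 0.01

    def test_long_time_limit(self):
        p = WellMixedParams(generation=65.0, ach=1.0, initial=400.0)
        c = rr.wellmixed_timeseries(p, [20.0 / p.lambda_total])[0]
        assert abs(c - rr.wellmixed_steady(p)) / rr.wellmixed_steady(p) < 1e-8

    def test_steady_initial_value_is_fixed_point(self):
        p0 = WellMixedParams(generation=65.0, ach=1.0)
        c_ss = rr.wellmixed_steady(p0)
        p = WellMixedParams(generation=65.0, ach=1.0, initial=c_ss)
        times = np.linspace(0, 50, 11)
        np.testing.assert_allclose(rr.wellmixed_timeseries(p, times), c_ss,
                                   rtol=1e-12)

    def test_monotone_approach_from_below(self):
        p = WellMixedParams(generation=65.0, ach=1.0, initial=0.0)
        series = rr.wellmixed_timeseries(p, np.linspace(0, 10, 50))
        assert np.all(np.diff(series) > 0)

    def test_negative_time_rejected(self):
        p = WellMixedParams(generation=65.0, ach=1.0)
        with pytest.raises(BoxModelError):
            rr.wellmixed_timeseries(p, [-1.0])


class TestCalibration:
    @given(extra=st.floats(0.0, 500.0), ach=st.floats(0.05, 5.0))
    def test_round_trip_identity(self, extra, ach):
        # any feasible observation: at or above the outdoor-supported floor
        c = ach * 10.0 / (ach + LAMBDA_RN_PER_H) + extra
        g = rr.calibrate_generation(c, ach, outdoor=10.0)
        p = WellMixedParams(generation=g, ach=ach, outdoor=10.0)
        assert rr.wellmixed_steady(p) == pytest.approx(c, rel=1e-10)

    def test_outdoor_floor_gives_zero_generation(self):
        ach, out = 1.0, 10.0
        floor = ach * out / (ach + LAMBDA_RN_PER_H)
        assert rr.calibrate_generation(floor, ach, out) == pytest.approx(
            0.0, abs=1e-9)

    def test_infeasible_observation_rejected(self):
        with pytest.raises(BoxModelError, match="outdoor-supported floor"):
            rr.calibrate_generation(1.0, 1.0, outdoor=10.0)


class TestDose:
    @pytest.mark.parametrize("conc,printed", [
        (70.21, 0.68), (66.25, 0.64), (170.7, 1.63), (154.0, 1.48)])
    def test_reference_doses_within_rounding_band(self, conc, printed):
        aed = rr.annual_effective_dose(conc)
        assert abs(aed - printed) <= 0.01

    def test_zero_concentration(self):
        assert rr.annual_effective_dose(0.0) == 0.0

    @given(c=st.floats(1.0, 500.0), s=st.floats(0.1, 4.0))
    def test_linearity(self, c, s):
        assert rr.annual_effective_dose(s * c) == pytest.approx(
            s * rr.annual_effective_dose(c), rel=1e-12)
        d = DoseParams(occupancy_h=1000.0)
        assert rr.annual_effective_dose(c, d) == pytest.approx(
            0.5 * rr.annual_effective_dose(c), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(BoxModelError):
            DoseParams(equilibrium_factor=0.0)
        with pytest.raises(BoxModelError):
            DoseParams(occupancy_h=9000.0)


def test_steady_concentration_table_layout():
    g = rr.calibrate_generation(221.60, 0.3, 10.0)
    rows = steady_concentration_table(g, SWEEP, dose=DoseParams())
    assert [r["ach_per_h"] for r in rows] == sorted(SWEEP)
    assert all("aed_msv_per_yr" in r for r in rows)
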