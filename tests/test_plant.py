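"""Gas-path physics: valve mixing, dilution integration, sensors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihtwin.errors import ActuationError, StabilityError, ValidationError
from ihtwin.plant import (
    AIR_O2_FRACTION,
    NITROGEN_O2_FRACTION,
    CompartmentState,
    GasSource,
    Sensor,
    SensorSpec,
    ValveSpec,
    air_source,
    analytic_dilution,
    mix_inflow,
    nitrogen_source,
    sense,
    step_compartment,
)


def prop_valve(source, max_flow, command, min_command=0.0):
    return ValveSpec("proportional", source, max_flow, command, min_command)


class TestMixInflow:
    def test_single_source_identity(self):
        q, o2 = mix_inflow([prop_valve(air_source(), 50.0, 1.0)])
        assert q == pytest.approx(50.0)
        assert o2 == pytest.approx(0.21)

    def test_two_source_mass_balance(self):
        # hand mass balance: (25*0.21 + 25*0.00004) / 50
        valves = [prop_valve(air_source(), 25.0, 1.0),
                  prop_valve(nitrogen_source(), 25.0, 1.0)]
        q, o2 = mix_inflow(valves)
        assert q == pytest.approx(50.0)
        assert o2 == pytest.approx(0.10502)

    def test_zero_flow_returns_sentinel(self):
        q, o2 = mix_inflow([prop_valve(air_source(), 50.0, 0.0)])
        assert q == 0.0
        assert math.isnan(o2)

    def test_min_command_floor(self):
        v = prop_valve(air_source(), 10.0, 0.0, min_command=0.3)
        assert v.flow_lpm() == pytest.approx(3.0)

    def test_on_off_valve_is_binary(self):
        v = ValveSpec("on_off", air_source(), 40.0)
        assert v.flow_lpm(0.0) == 0.0
        assert v.flow_lpm(1.0) == 40.0

    def test_empty_valve_list_rejected(self):
        with pytest.raises(ActuationError):
            mix_inflow([])

    def test_out_of_range_command_rejected(self):
        with pytest.raises(ActuationError):
            prop_valve(air_source(), 50.0, 1.0).flow_lpm(1.5)


class TestStepCompartment:
    def test_equilibrium_is_fixed_point(self):
        s = CompartmentState(12.4, 0.21)
        out = step_compartment(s, 50.0, 0.21, 0.01)
        assert out.o2_fraction == pytest.approx(0.21)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValidationError):
            step_compartment(CompartmentState(12.4, 0.21), 50.0, 0.0, -0.1)

    def test_stability_guard(self):
        with pytest.raises(StabilityError):
            step_compartment(CompartmentState(0.05, 0.21), 50.0, 0.0, 10.0)

    def test_e_folding_matches_closed_form(self):
        # V/Q = 12.4/50 min = 14.88 s; after one e-fold C = 0.21/e
        s = CompartmentState(12.4, 0.21)
        dt, t_total = 0.001, 14.88
        for _ in range(round(t_total / dt)):
            s = step_compartment(s, 50.0, 0.0, dt)
        assert s.o2_fraction == pytest.approx(0.21 / math.e, abs=1e-4)

    def test_euler_tracks_analytic_over_a_minute(self):
        s = CompartmentState(12.4, 0.21)
        dt = 0.01
        worst = 0.0
        for i in range(round(60.0 / dt)):
            s = step_compartment(s, 50.0, 0.0, dt)
            ref = analytic_dilution(0.21, 0.0, 50.0, 12.4, (i + 1) * dt)
            worst = max(worst, abs(s.o2_fraction - ref))
        assert worst < 1e-4

    @given(c0=st.floats(0.0, 0.21), c_in=st.floats(0.0, 0.21),
           q=st.floats(0.1, 50.0), n=st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_containment_and_monotone_approach(self, c0, c_in, q, n):
        """Each step stays between the old value and the inflow, and the
        distance to the inflow concentration never grows."""
        s = CompartmentState(2.0, c0)
        gap = abs(c0 - c_in)
        for _ in range(n):
            prev = s.o2_fraction
            s = step_compartment(s, q, c_in, 0.01)
            assert min(prev, c_in) - 1e-12 <= s.o2_fraction <= max(prev, c_in) + 1e-12
            new_gap = abs(s.o2_fraction - c_in)
            assert new_gap <= gap + 1e-12
            gap = new_gap


class TestAnalyticDilution:
    def test_initial_value(self):
        assert analytic_dilution(0.21, 0.0, 50.0, 12.4, 0.0) == pytest.approx(0.21)

    def test_no_flow_no_change(self):
        assert analytic_dilution(0.21, 0.0, 0.0, 12.4, 1e6) == pytest.approx(0.21)

    def test_e_folding_value(self):
        assert analytic_dilution(0.21, 0.0, 50.0, 12.4, 14.88) == pytest.approx(
            0.21 / math.e, rel=1e-3)

    def test_limit_is_inflow(self):
        assert analytic_dilution(0.21, 0.057, 50.0, 12.4, 1e5) == pytest.approx(0.057)

    def test_invalid_geometry(self):
        with pytest.raises(ValidationError):
            analytic_dilution(0.21, 0.0, 50.0, -1.0, 1.0)


class TestSensor:
    def test_ideal_sensor_is_identity(self):
        spec = SensorSpec(time_constant_s=0.0, noise_sd=0.0, adc_bits=24)
        s = Sensor(spec, initial=0.0)
        assert sense(0.21, s, 0.1) == pytest.approx(0.21, abs=2e-8)

    def test_first_order_step_response(self):
        # reading at t = tau is 1 - 1/e of the step
        spec = SensorSpec(time_constant_s=5.0, noise_sd=0.0, adc_bits=24)
        s = Sensor(spec, initial=0.0)
        dt = 0.001
        for _ in range(round(5.0 / dt)):
            s.advance(0.21, dt)
        assert s.sample() == pytest.approx(0.21 * (1 - 1 / math.e), abs=1e-3)

    def test_quantization_resolution(self):
        spec = SensorSpec(adc_bits=10, adc_range=0.25)
        assert spec.resolution == pytest.approx(0.25 / 1024)
        s = Sensor(SensorSpec(time_constant_s=0.0, noise_sd=0.0, adc_bits=10,
                              adc_range=0.25), initial=0.0)
        r = sense(0.21, s, 0.1)
        assert abs(r - 0.21) <= spec.resolution / 2

    def test_reading_saturates_at_adc_range(self):
        s = Sensor(SensorSpec(time_constant_s=0.0, noise_sd=0.0), initial=0.0)
        assert sense(0.9, s, 0.1) == pytest.approx(0.25)

    def test_noise_is_seeded(self):
        spec = SensorSpec(time_constant_s=0.0, noise_sd=1e-3)
        a = sense(0.1, Sensor(spec, 0.1), 0.1, np.random.default_rng(7))
        b = sense(0.1, Sensor(spec, 0.1), 0.1, np.random.default_rng(7))
        assert a == b


class TestDomainTypes:
    def test_source_fraction_bounds(self):
        with pytest.raises(ValidationError):
            GasSource("air", 1.5, 1.2)

    def test_source_constants(self):
        assert air_source().o2_fraction == AIR_O2_FRACTION == 0.21
        assert nitrogen_source().o2_fraction == NITROGEN_O2_FRACTION == 0.00004

    def test_compartment_bounds(self):
        with pytest.raises(ValidationError):
            CompartmentState(-1.0, 0.21)
        with pytest.raises(ValidationError):
            CompartmentState(12.4, 1.2)
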