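"""Trajectory core: unit conversion, volume, steady state, closed form and
its limit branches, checked against the mass-balance ODE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crkinetics import (
    FlowRate,
    InvalidScenarioError,
    InvalidUnitError,
    KineticScenario,
    NoSteadyStateError,
    VolumeExhaustedError,
    convert_flow,
    cr_at_time,
    ode_residual,
    steady_state_cr,
    volume_at_time,
)

from conftest import random_scenarios


class TestFlowConversion:
    @pytest.mark.parametrize(
        "value, unit, target, expected",
        [
            (3.5, "L/h", "mL/min", 3.5 * 50.0 / 3.0),  # 58.33...
            (100.0, "mL/min", "L/h", 6.0),
            (0.0, "L/h", "mL/min", 0.0),
            (-0.3, "L/h", "mL/min", -5.0),
        ],
    )
    def test_examples(self, value, unit, target, expected):
        out = convert_flow(FlowRate(value, unit), target)
        assert out.unit == target
        assert out.value == pytest.approx(expected, rel=1e-15)

    def test_top_domain_threshold_value(self):
        # 2*V0/t for V0=42 L, t=24 h converts to 58.3(3) mL/min
        out = convert_flow(FlowRate(2 * 42 / 24, "L/h"), "mL/min")
        assert out.value == pytest.approx(58.3333333333, rel=1e-10)

    @given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_is_identity(self, x):
        back = convert_flow(convert_flow(FlowRate(x, "L/h"), "mL/min"), "L/h")
        assert back.value == pytest.approx(x, rel=1e-14, abs=1e-300)

    def test_unknown_unit_rejected(self):
        with pytest.raises(InvalidUnitError):
            FlowRate(1.0, "gallons/fortnight")
        with pytest.raises(InvalidUnitError):
            convert_flow(FlowRate(1.0, "L/h"), "mL/h")


class TestVolume:
    def test_linear_decline(self):
        s = KineticScenario(v0=42, dvdt=-0.3, t=24, gfr_k=80, gen=40, cr0=8)
        assert volume_at_time(s) == pytest.approx(34.8)

    def test_constant_volume(self):
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=40, cr0=8)
        for tt in (0, 7, 24):
            assert volume_at_time(s, tt) == 42.0

    def test_exhaustion_rejected_at_construction(self):
        # dvdt = -V0/t = -1.75 L/h drains the volume exactly at the horizon
        with pytest.raises(VolumeExhaustedError):
            KineticScenario(v0=42, dvdt=-1.75, t=24, gfr_k=80, gen=40, cr0=8)

    def test_invalid_parameters_rejected(self):
        good = dict(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=40, cr0=8)
        for bad in ({"v0": 0}, {"t": -1}, {"gfr_k": -5}, {"gen": -1}, {"cr0": 0}):
            with pytest.raises(InvalidScenarioError):
                KineticScenario(**{**good, **bad})


class TestSteadyState:
    def test_gen_over_clearance(self):
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=100, gen=100, cr0=1)
        assert steady_state_cr(s) == pytest.approx(1.0)

    def test_volume_rate_included(self):
        s = KineticScenario(v0=42, dvdt=-0.1, t=24, gfr_k=80, gen=40, cr0=8)
        assert steady_state_cr(s) == pytest.approx(40 / (80 - 0.1 * 50 / 3), rel=1e-12)
        assert steady_state_cr(s) == pytest.approx(0.51064, abs=5e-6)

    def test_zero_denominator_is_error(self):
        s = KineticScenario(v0=42, dvdt=-4.8, t=8, gfr_k=80, gen=40, cr0=8)
        with pytest.raises(NoSteadyStateError):
            steady_state_cr(s)


class TestTrajectory:
    def test_crrt_worked_value(self):
        s = KineticScenario(v0=42, dvdt=-0.1, t=24, gfr_k=80, gen=40, cr0=8)
        assert cr_at_time(s) == pytest.approx(0.982, abs=1e-3)

    @given(
        v0=st.floats(20, 60),
        dvdt=st.floats(-0.5, 1.0),
        gfr_k=st.floats(0, 150),
        gen=st.floats(0, 150),
        cr0=st.floats(0.5, 15),
    )
    @settings(max_examples=100, derandomize=True)
    def test_initial_condition(self, v0, dvdt, gfr_k, gen, cr0):
        s = KineticScenario(v0=v0, dvdt=dvdt, t=0.0, gfr_k=gfr_k, gen=gen, cr0=cr0)
        assert cr_at_time(s) == cr0

    def test_steady_start_stays_flat(self):
        # dvdt=0 and Gen = GFR_K*Cr0: the initial state is the steady state
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=80 * 8, cr0=8)
        for tt in (0.5, 6, 24):
            assert cr_at_time(s, tt) == pytest.approx(8.0, rel=1e-12)

    def test_classic_fixed_volume_kinetics(self):
        # with dvdt=0 the solution must collapse to the single-exponential
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=40, cr0=8)
        g = s.gfr_k_lh
        exact = s.cr0 * math.exp(-g * s.t / s.v0) + (s.gen / s.gfr_k) * (
            1 - math.exp(-g * s.t / s.v0)
        )
        assert cr_at_time(s) == pytest.approx(exact, rel=1e-10)

    def test_positive_and_finite_on_random_scenarios(self):
        rng = np.random.default_rng(7)
        for s in random_scenarios(rng, 50):
            v = cr_at_time(s)
            assert math.isfinite(v) and v > 0


def _general_formula(v0, dvdt, t, gfr_k, gen, cr0):
    """The raw closed form, no limit-branch dispatch (test oracle)."""
    expo = 1.0 + (gfr_k * 3.0 / 50.0) / dvdt
    frac = 1.0 - (v0 / (v0 + dvdt * t)) ** expo
    return cr0 + frac * (gen / (gfr_k + dvdt * 50.0 / 3.0) - cr0)


class TestLimitBranches:
    @pytest.mark.parametrize("eps", [1e-3, 1e-6])
    def test_dvdt_to_zero_continuity(self, eps):
        args = dict(v0=42.0, t=24.0, gfr_k=80.0, gen=40.0, cr0=8.0)
        limit = cr_at_time(KineticScenario(dvdt=0.0, **args))
        for sign in (+1, -1):
            general = _general_formula(dvdt=sign * eps, **args)
            rel = abs(general - limit) / limit
            assert rel < 200 * eps  # -> 0 linearly with eps

    def test_dvdt_branch_matches_general_formula_at_1e9(self):
        args = dict(v0=42.0, t=24.0, gfr_k=80.0, gen=40.0, cr0=8.0)
        limit = cr_at_time(KineticScenario(dvdt=0.0, **args))
        assert abs(_general_formula(dvdt=1e-9, **args) - limit) / limit < 1e-6

    @pytest.mark.parametrize("eps", [1e-3, 1e-6])
    def test_clearance_cancellation_continuity(self, eps):
        # GFR_K + dvdt -> 0 (in L/h): branch vs general formula nearby
        args = dict(v0=42.0, t=4.0, gen=40.0, cr0=8.0, gfr_k=80.0)
        branch = cr_at_time(KineticScenario(dvdt=-4.8, **args))
        general = _general_formula(dvdt=-4.8 + eps, **args)
        rel = abs(general - branch) / branch
        assert rel < 100 * eps

    def test_pure_accumulation(self):
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=0.0, gen=40, cr0=8)
        assert cr_at_time(s) == pytest.approx(8 + 40 * (3 / 50) * 24 / 42, rel=1e-12)


class TestOdeResidual:
    def test_worked_scenario_interior_time(self):
        s = KineticScenario(v0=42, dvdt=-0.1, t=24, gfr_k=80, gen=40, cr0=8)
        assert abs(ode_residual(s, 12.0, h=1e-3)) < 1e-5

    def test_fixed_volume_branch(self):
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=40, cr0=8)
        assert abs(ode_residual(s, 6.0, h=1e-3)) < 1e-5

    def test_steady_state_residual_is_zero(self):
        s = KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=80 * 8, cr0=8)
        assert abs(ode_residual(s, 6.0)) < 1e-10

    def test_random_scenarios_all_branches(self):
        # the closed form must satisfy the mass balance everywhere sampled
        rng = np.random.default_rng(11)
        scenarios = random_scenarios(rng, 100)
        # force coverage of the limit branches
        scenarios += [
            KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=80, gen=40, cr0=8),
            KineticScenario(v0=42, dvdt=-4.8, t=4, gfr_k=80, gen=40, cr0=8),
            KineticScenario(v0=42, dvdt=0.0, t=24, gfr_k=0.0, gen=40, cr0=8),
        ]
        for s in scenarios:
            for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
                tt = frac * s.t
                assert abs(ode_residual(s, tt, h=1e-3)) < 1e-4, s
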