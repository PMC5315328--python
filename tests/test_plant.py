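"""Plant model: activation driver, Starling law, valves, mass balance,
equilibrium oracle and whole-run conservation."""

import math

import numpy as np
import pytest

from slcsim.controllers import ConstantSpeedController
from slcsim.plant import (CVSParameters, CVSState, derivatives,
                          elastance_driver, equilibrium_state,
                          fluid_shift_flow, initial_state, integrate,
                          lv_edpvr, mean_filling_pressure, rv_edpvr,
                          starling_elastance, valve_flow, compute_pressures)
from slcsim.pump import PumpParameters
from slcsim.scenarios import build_scenario


class TestElastanceDriver:
    def test_zero_at_beat_onset(self):
        assert elastance_driver(0.0, 60.0, 0.35) == 0.0

    @pytest.mark.parametrize("hr", [60.0, 90.0, 65.0])
    def test_normalised_single_peak(self, hr):
        period = 60.0 / hr
        phases = np.linspace(0.0, period, 4001, endpoint=False)
        act = np.array([elastance_driver(p, hr, 0.35) for p in phases])
        assert act.max() == pytest.approx(1.0, abs=1e-6)
        assert act.min() == 0.0
        # single maximum: activation rises then falls within systole
        sys_mask = phases < 0.35 * period
        d = np.diff(act[sys_mask])
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
        # diastole flat at zero
        assert np.all(act[~sys_mask] == 0.0)

    def test_period_scales_with_heart_rate(self):
        # waveform at HR=90 compressed by 60/90 relative to HR=60
        assert elastance_driver(0.3, 60.0, 0.35) == pytest.approx(
            elastance_driver(0.2, 90.0, 0.35), rel=1e-12)

    def test_rejects_nonpositive_heart_rate(self):
        with pytest.raises(ValueError):
            elastance_driver(0.1, 0.0, 0.35)


class TestStarlingElastance:
    def test_anchored_at_reference_preload(self):
        assert starling_elastance(7.5, 0.5, 0.15, ref=7.5) == 0.5

    def test_monotone_and_saturating(self):
        preloads = np.linspace(-5.0, 40.0, 50)
        e = [starling_elastance(p, 0.5, 0.15, ref=7.5, lo=0.2, hi=2.2)
             for p in preloads]
        assert all(b >= a for a, b in zip(e, e[1:]))
        assert e[-1] == pytest.approx(0.5 * 2.2)
        assert e[0] == pytest.approx(0.5 * 0.2)

    def test_zero_gain_degenerates_to_base(self):
        for p in (-3.0, 0.0, 7.5, 30.0):
            assert starling_elastance(p, 0.5, 0.0) == 0.5

    def test_rejects_negative_base(self):
        with pytest.raises(ValueError):
            starling_elastance(5.0, -1.0, 0.1)


class TestValveFlow:
    def test_ohmic_forward_branch(self):
        assert valve_flow(15.0, 5.0, 0.01) == pytest.approx(1000.0)

    @pytest.mark.parametrize("dp", [-5.0, 0.0])
    def test_closed_for_reverse_or_zero_gradient(self, dp):
        assert valve_flow(10.0 + dp, 10.0, 0.02) == 0.0

    def test_never_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            up, down = rng.normal(10, 20, 2)
            assert valve_flow(up, down, 0.03) >= 0.0

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError):
            valve_flow(10.0, 5.0, 0.0)


class TestEDPVR:
    def test_lv_negative_below_unstressed_volume(self):
        assert lv_edpvr(8.0, 10.0, 6.0, 25.0) < 0.0
        assert lv_edpvr(10.0, 10.0, 6.0, 25.0) == 0.0
        assert lv_edpvr(60.0, 10.0, 6.0, 25.0) > 0.0

    def test_lv_concave(self):
        v = np.linspace(15.0, 200.0, 100)
        p = np.array([lv_edpvr(x, 10.0, 6.0, 25.0) for x in v])
        slopes = np.diff(p) / np.diff(v)
        assert np.all(np.diff(slopes) < 0.0)

    def test_rv_saturates_at_ceiling(self):
        assert rv_edpvr(5000.0, 20.0, 15.0, 0.0015) < 15.0
        assert rv_edpvr(5000.0, 20.0, 15.0, 0.0015) == pytest.approx(
            15.0, rel=1e-3)


class TestDerivatives:
    def params(self):
        return CVSParameters()

    def test_equilibrium_when_pressures_equal_and_no_pump(self):
        p = self.params()
        # build a state where every chamber sits at the same pressure
        pr = {k: 5.0 for k in ("p_la", "p_lv", "p_sa", "p_sv", "p_ra",
                               "p_rv", "p_pa", "p_pv")}
        st = initial_state(p, pressures=pr)
        st.lv_ees_eff = 0.0
        st.rv_ees_eff = 0.0
        st.phase = 0.9 * p.period      # diastole: activation = 0
        d = derivatives(st, p, pump_flow=0.0, t=0.0)
        assert np.allclose(d[:9], 0.0, atol=1e-9)

    def test_volume_conservation_of_mass_balance(self):
        p = self.params()
        st = initial_state(p)
        d = derivatives(st, p, pump_flow=4.5, t=0.0, shift_flow=10.0)
        # sum over circuit + reservoir is zero regardless of flows
        assert sum(d[:9]) == pytest.approx(0.0, abs=1e-12)

    def test_pump_path_moves_volume_lv_to_aorta(self):
        p = self.params()
        pr = {k: 5.0 for k in ("p_la", "p_lv", "p_sa", "p_sv", "p_ra",
                               "p_rv", "p_pa", "p_pv")}
        st = initial_state(p, pressures=pr)
        st.lv_ees_eff = 0.0
        st.rv_ees_eff = 0.0
        st.phase = 0.9 * p.period
        q = 3.0  # L/min
        d = derivatives(st, p, pump_flow=q, t=0.0)
        assert d[1] == pytest.approx(-q * 1000.0 / 60.0)   # LV drains
        assert d[2] == pytest.approx(+q * 1000.0 / 60.0)   # aorta gains

    def test_nan_state_raises(self):
        p = self.params()
        st = initial_state(p)
        st.v_lv = float("nan")
        with pytest.raises(FloatingPointError):
            derivatives(st, p, 0.0, 0.0)


class TestFluidShift:
    def test_ramp_transfers_exact_volume(self):
        dt = 5e-4
        t = np.arange(0, 30, dt)
        flow = np.array([fluid_shift_flow(700.0, 20.0, 5.0, x) for x in t])
        assert np.sum(flow) * dt == pytest.approx(700.0, rel=1e-6)
        assert np.all(flow[t < 5.0] == 0.0)
        assert np.all(flow[t >= 25.0] == 0.0)

    def test_negative_volume_drains_circuit(self):
        assert fluid_shift_flow(-300.0, 20.0, 0.0, 10.0) == pytest.approx(
            -15.0)

    def test_zero_volume_is_identity(self):
        assert fluid_shift_flow(0.0, 20.0, 0.0, 10.0) == 0.0

    def test_duration_bounds_enforced(self):
        with pytest.raises(ValueError):
            fluid_shift_flow(100.0, 25.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            fluid_shift_flow(100.0, 0.0, 0.0, 1.0)


class TestEquilibriumOracle:
    def test_relaxed_plant_matches_mean_filling_pressure(self):
        """With no beats and no pump, the ODE steady state must match the
        closed-form mean circulatory filling pressure within 0.5%."""
        p = CVSParameters()
        st = equilibrium_state(p)
        target = mean_filling_pressure(st, p)
        pr = compute_pressures(st, p, act=0.0)
        for name in ("p_la", "p_sa", "p_sv", "p_ra", "p_pa", "p_pv",
                     "p_lv", "p_rv"):
            assert pr[name] == pytest.approx(target, rel=5e-3), name


class TestIntegrate:
    def test_zero_duration_gives_empty_trace(self):
        p = CVSParameters()
        tr = integrate(initial_state(p), p, ConstantSpeedController(2100.0),
                       PumpParameters(), None, duration=0.0)
        assert len(tr) == 0

    def test_rejects_coarse_time_step(self):
        p = CVSParameters()
        with pytest.raises(ValueError):
            integrate(initial_state(p), p, ConstantSpeedController(2100.0),
                      PumpParameters(), None, duration=1.0, dt=2e-3)

    def test_volume_conservation_over_full_run_with_shift(self):
        """Total fluid (circuit + reservoir) is conserved to < 1 mL over a
        240 s exercise run including the 700 mL scripted shift."""
        p = CVSParameters()
        st = initial_state(p)
        total0 = st.circuit_volume + st.v_reservoir
        integrate(st, p, ConstantSpeedController(2100.0), PumpParameters(),
                  build_scenario("exercise"), duration=240.0)
        total1 = st.circuit_volume + st.v_reservoir
        assert abs(total1 - total0) < 1.0
        assert st.shifted_volume == pytest.approx(700.0, abs=1e-6)
        # and the reservoir lost exactly the shifted amount
        assert st.v_reservoir == pytest.approx(
            p.reservoir_volume - 700.0, abs=1.0)

    def test_plant_starling_response_monotone_in_volume(self):
        """At fixed pump speed, more circulating volume means more output."""
        means = []
        for p_sv in (5.0, 7.5, 10.0):
            p = CVSParameters()
            st = initial_state(p, pressures={"p_sv": p_sv})
            tr = integrate(st, p, ConstantSpeedController(2100.0),
                           PumpParameters(), None, duration=40.0)
            means.append(float(np.mean(tr["q_sys"][-20000:])))
        assert means[0] < means[1] < means[2]

    def test_steady_state_flow_balance(self, scenario_run):
        """Mean systemic flow = mean pulmonary flow = mean pump+valve
        output over the settled end of the baseline run (within 2%)."""
        tr = scenario_run("baseline", "csc").trace
        w = tr.window(tr.duration - 30.0, tr.duration)
        q_sys = float(np.mean(w["q_sys"]))
        q_pulm = float(np.mean(w["q_pulm"]))
        assert q_sys == pytest.approx(q_pulm, rel=0.02)
        assert q_sys == pytest.approx(float(np.mean(w["q_pump"])), rel=0.05)

    def test_blowup_aborts_with_diagnostic(self):
        p = CVSParameters()
        st = initial_state(p)
        st.v_sa = float("nan")
        with pytest.raises(FloatingPointError):
            integrate(st, p, ConstantSpeedController(2100.0),
                      PumpParameters(), None, duration=0.01)
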