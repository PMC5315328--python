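"""Control line, signal conditioning, PID and the two controllers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slcsim.controllers import (ConstantSpeedController, ControlLine,
                                LowPassFilter, MovingAverage, PIDGains,
                                StarlingLikeController, control_line_eval,
                                control_line_slope, csc_command,
                                lowpass_update, sample_plved,
                                sample_plved_series)
from slcsim.fixtures import FixtureSpec, generate_trace


class TestControlLine:
    @pytest.mark.parametrize("plved,expected", [
        (7.4, 5.4105),   # hand evaluation of the printed cubic
        (15.0, 8.6822),
    ])
    def test_hand_evaluated_points(self, plved, expected):
        assert control_line_eval(plved, ControlLine()) == pytest.approx(
            expected, abs=1e-4)

    def test_zero_scaling_gives_zero_everywhere(self):
        line = ControlLine(k=0.0)
        for p in np.linspace(-5, 25, 40):
            assert control_line_eval(p, line) == 0.0

    def test_linear_in_scaling_factor(self):
        l1, l2 = ControlLine(k=1.0), ControlLine(k=2.0)
        for p in np.linspace(1.0, 20.0, 30):   # above the zero-floor knee
            assert control_line_eval(p, l2) == pytest.approx(
                2.0 * control_line_eval(p, l1))

    def test_strictly_increasing_on_clinical_range(self):
        line = ControlLine()
        p = np.linspace(0.0, 20.0, 2001)
        q = np.array([control_line_eval(x, line) for x in p])
        # strictly increasing once above the zero floor
        above = q > 0
        assert np.all(np.diff(q[above]) > 0)
        assert np.all(np.array([control_line_slope(x, line)
                                for x in np.linspace(0.5, 20, 100)]) > 0)

    def test_flat_slope_at_high_preload(self):
        line = ControlLine()
        assert control_line_slope(15.0, line) < control_line_slope(5.0, line)

    def test_negative_cubic_region_floored_at_zero(self):
        assert control_line_eval(0.0, ControlLine()) == 0.0


class TestLowPass:
    def test_dc_gain_exactly_one(self):
        f = LowPassFilter(0.25, initial=3.3)
        for _ in range(1000):
            y = f.update(3.3, 5e-4)
        assert y == 3.3

    def test_step_reaches_63_percent_at_time_constant(self):
        dt = 5e-4
        f = LowPassFilter(0.25, initial=0.0)
        tau = 1.0 / (2 * math.pi * 0.25)
        n = int(round(tau / dt))
        for _ in range(n):
            y = f.update(1.0, dt)
        assert y == pytest.approx(1.0 - math.exp(-1.0), abs=5e-3)

    def test_half_power_at_cutoff_frequency(self):
        dt, fc = 5e-4, 0.25
        f = LowPassFilter(fc, initial=0.0)
        t = np.arange(0, 60, dt)
        out = np.array([f.update(math.sin(2 * math.pi * fc * x), dt)
                        for x in t])
        amp = out[int(40 / dt):].max()          # settled amplitude
        assert amp == pytest.approx(1 / math.sqrt(2), rel=2e-2)

    def test_functional_form_matches_class(self):
        f = LowPassFilter(0.25, initial=2.0)
        y_cls = f.update(5.0, 5e-4)
        assert lowpass_update(2.0, 5.0, 5e-4, 0.25) == pytest.approx(y_cls)


class TestMovingAverage:
    def test_constant_input_passthrough(self):
        ma = MovingAverage(1.0, 5e-4, initial=4.2)
        for _ in range(3000):
            y = ma.update(4.2)
        assert y == pytest.approx(4.2)

    def test_full_period_sinusoid_cancels(self):
        dt = 5e-4
        ma = MovingAverage(1.0, dt)
        t = np.arange(0, 3, dt)
        for x in t:
            y = ma.update(math.sin(2 * math.pi * 1.0 * x))
        assert abs(y) < 1e-3

    def test_unit_step_ramps_linearly_to_one(self):
        dt = 5e-4
        ma = MovingAverage(1.0, dt, initial=0.0)
        ys = [ma.update(1.0) for _ in range(int(1.0 / dt))]
        assert ys[-1] == pytest.approx(1.0)
        assert ys[int(0.5 / dt) - 1] == pytest.approx(0.5, abs=2e-3)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=400),
           st.integers(2, 50))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_windowed_mean(self, xs, n):
        """Ring-buffer running mean equals a naive trailing-window mean."""
        dt = 1.0
        ma = MovingAverage(float(n), dt)
        for i, x in enumerate(xs):
            got = ma.update(x)
            expect = float(np.mean(xs[max(0, i - n + 1): i + 1]))
            assert got == pytest.approx(expect, abs=1e-9)


class TestSamplePlved:
    def test_constant_pressure_returns_constant(self):
        p_lv = np.full(8000, 10.0)
        onsets = np.array([0.0, 1.0, 2.0, 3.0])
        assert sample_plved(p_lv, onsets, 5e-4) == 10.0

    def test_injected_sequence_round_trip(self):
        """A fixture with a known per-beat PLVED staircase is recovered
        exactly by the preload sampler."""
        seq = [6.0, 7.5, 9.0, 4.0, 11.0, 8.0]
        spec = FixtureSpec(duration=6.0, heart_rate=60.0,
                           noise_sd_pressure=0.0, noise_sd_flow=0.0,
                           plved_sequence=seq)
        tr = generate_trace(spec)
        times, values = sample_plved_series(tr["p_lv"], tr.beat_onsets,
                                            tr.dt)
        # onset of beat i+1 samples the diastolic level of beat i
        assert list(values) == pytest.approx(seq[:len(values)])

    def test_negative_end_diastolic_pressure_passes_through(self):
        p_lv = np.full(8000, -0.5)
        onsets = np.array([0.0, 1.0])
        assert sample_plved(p_lv, onsets, 5e-4) == -0.5

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            sample_plved(np.array([]), np.array([0.0, 1.0]), 5e-4)

    def test_no_completed_beat_rejected(self):
        with pytest.raises(ValueError):
            sample_plved(np.full(100, 5.0), np.array([0.0]), 5e-4)


class TestPID:
    def test_zero_error_from_rest_returns_measured_speed(self):
        slc = StarlingLikeController(initial_speed=2100.0,
                                     initial_plved=7.5)
        q0 = slc.reference
        # feed the exact reference flow and a steady plant
        cmd = None
        for i in range(4000):
            cmd = slc.step(i * 5e-4, 7.5, q0, 2100.0, new_beat=False)
        assert cmd == pytest.approx(2100.0, abs=1e-6)

    def test_integral_action_matches_closed_form(self):
        """With KP = KD = 0 and a 1 L/min step disturbance in measured
        flow, the integral correction follows the closed form
        KI * (t - tau*(1 - exp(-t/tau))): the error seen by the
        integrator is the step passed through the 0.25 Hz measurement
        low-pass of time constant tau."""
        gains = PIDGains(kp=0.0, ki=162.5, kd=0.0)
        slc = StarlingLikeController(gains=gains, initial_speed=2100.0,
                                     initial_plved=7.5, max_speed=10000.0)
        ref = slc.reference
        t_end = 2.0
        n = int(t_end / gains.period)
        for i in range(n):
            # measured flow 1 L/min below the reference; speed held
            cmd = slc.step(i * gains.period, 7.5, ref - 1.0, 2100.0, False)
        tau = 1.0 / (2.0 * math.pi * 0.25)
        expected = 162.5 * (t_end - tau * (1.0 - math.exp(-t_end / tau)))
        assert cmd - 2100.0 == pytest.approx(expected, rel=1e-2)

    def test_command_never_below_minimum_speed(self):
        slc = StarlingLikeController(initial_speed=2100.0,
                                     initial_plved=7.5)
        # large negative error drives the command into the clamp
        for i in range(8000):
            cmd = slc.step(i * 5e-4, 7.5, 20.0, 1800.0, False)
        assert cmd == 1800.0

    def test_anti_windup_releases_quickly(self):
        """After a long clamp at minimum speed, a reversed error brings
        the command off the clamp without waiting for a wound-up
        integrator to unwind."""
        slc = StarlingLikeController(initial_speed=2100.0,
                                     initial_plved=7.5)
        for i in range(20000):                       # 10 s of clamping
            slc.step(i * 5e-4, 7.5, 20.0, 1800.0, False)
        assert slc.pid.command == 1800.0
        steps_to_release = None
        for i in range(20000):
            cmd = slc.step((20000 + i) * 5e-4, 7.5, 0.0, 1800.0, False)
            if cmd > 1800.0:
                steps_to_release = i
                break
        assert steps_to_release is not None and steps_to_release < 6000

    def test_invalid_gains_rejected(self):
        with pytest.raises(ValueError):
            PIDGains(kp=-1.0)
        with pytest.raises(ValueError):
            PIDGains(period=0.0)


class TestConstantSpeed:
    def test_commands_set_speed_regardless_of_state(self):
        csc = ConstantSpeedController(2100.0)
        for p_lv in (-5.0, 0.0, 50.0):
            assert csc.step(0.0, p_lv, 9.9, 1234.0, True) == 2100.0

    def test_custom_set_speed(self):
        assert ConstantSpeedController(1800.0).set_speed == 1800.0

    def test_set_speed_below_minimum_clamped(self):
        assert csc_command(1500.0) == 1800.0
        assert ConstantSpeedController(1500.0).set_speed == 1800.0


class TestClosedLoop:
    def test_slc_settles_on_the_control_line(self, scenario_run):
        """At steady state the SLC operating point lies on the Eq-1-style
        control line: measured mean flow equals the line evaluated at the
        measured mean PLVED (within 2%)."""
        res = scenario_run("baseline", "slc")
        f = res.final_summary
        plved = f["PLVED_mmHg"]["mean"]
        qp = f["QP_L_min"]["mean"]
        assert qp == pytest.approx(
            control_line_eval(plved, ControlLine()), rel=0.02)

    def test_exercise_raises_and_blood_loss_lowers_speed(self, scenario_run):
        ex = scenario_run("exercise", "slc")
        bl = scenario_run("blood_loss", "slc")
        assert (ex.final_summary["speed_rpm"]["mean"]
                > ex.baseline_summary["speed_rpm"]["mean"])
        assert (bl.final_summary["speed_rpm"]["mean"]
                < bl.baseline_summary["speed_rpm"]["mean"])

    @pytest.mark.parametrize("scenario", ["baseline", "exercise",
                                          "blood_loss", "lvc_reduction"])
    def test_speed_never_below_minimum_in_any_run(self, scenario_run,
                                                  scenario):
        for controller in ("slc", "csc"):
            tr = scenario_run(scenario, controller).trace
            assert float(tr["speed_rpm"].min()) >= 1800.0 - 1e-6
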