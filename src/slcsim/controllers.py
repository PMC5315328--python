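"""Pump-speed controllers: Starling-like control (SLC) and constant speed.

The SLC emulates the Frank-Starling law of the native heart: the mean
left-ventricular end-diastolic pressure PLVED_m (the preload) is mapped
through a cubic *control line*

    Qref = K * (0.0003*p^3 - 0.0276*p^2 + 0.9315*p - 0.0928)   [L/min]

to a desired mean pump flow, and a PID loop adjusts the mean pump speed
until the measured mean flow matches it.  The cubic was fitted to
Guyton's canonical cardiac-output/filling-pressure data: it is steep at
low preload (rapid unloading backs off before ventricular suction) and
flat at high preload (avoids over-pumping).  The scaling factor K scales
the whole curve to a patient's preload sensitivity.

Signal conditioning follows the bench implementation: PLVED is sampled
once per beat at end-diastole, then low-pass filtered at 0.25 Hz; the
measured pump flow and speed are low-pass filtered at 0.25 Hz; the flow
reference passes a 1 s moving average before the PID.  The PID runs at a
0.5 ms sample period and produces a speed *correction* added to the
measured mean speed (the incremental form of the printed transfer
function); the command is clamped to [1800, max] rpm with integrator
hold while the clamp is active.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ControlLine", "PIDGains", "LowPassFilter", "MovingAverage",
    "control_line_eval", "control_line_slope", "sample_plved",
    "StarlingLikeController", "ConstantSpeedController",
    "FlowTrackingController", "csc_command",
]


@dataclass
class ControlLine:
    """Cubic preload -> reference-flow map with scaling factor K."""

    c3: float = 0.0003
    c2: float = -0.0276
    c1: float = 0.9315
    c0: float = -0.0928
    k: float = 1.0


def control_line_eval(plved_m: float, line: ControlLine) -> float:
    """Reference mean pump flow (L/min) for a given mean PLVED (mmHg).

    The raw cubic is negative for PLVED_m below ~0.1 mmHg; the output is
    floored at 0 (the 1800 rpm speed clamp is the true actuator bound).
    """
    p = plved_m
    q = line.k * (((line.c3 * p + line.c2) * p + line.c1) * p + line.c0)
    return q if q > 0.0 else 0.0


def control_line_slope(plved_m: float, line: ControlLine) -> float:
    """Derivative of the (un-floored) control line, L/min per mmHg."""
    p = plved_m
    return line.k * ((3.0 * line.c3 * p + 2.0 * line.c2) * p + line.c1)


@dataclass
class PIDGains:
    """Gains of the flow-tracking PID (error in L/min, output in rpm)."""

    kp: float = 130.0      # rpm.min/L
    ki: float = 162.5      # rpm.min/L/s
    kd: float = 58.5       # rpm.s.min/L
    period: float = 5e-4   # s

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be non-negative")
        if self.period <= 0:
            raise ValueError("sample period must be positive")


class LowPassFilter:
    """First-order discrete low-pass with exact unit DC gain.

    y <- y + (1 - exp(-dt/tau)) * (x - y), tau = 1/(2*pi*fc).
    """

    def __init__(self, cutoff_hz: float = 0.25,
                 initial: Optional[float] = None):
        if cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        self.tau = 1.0 / (2.0 * math.pi * cutoff_hz)
        self.y = initial

    def update(self, x: float, dt: float) -> float:
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.y is None:
            self.y = x
        else:
            self.y += (1.0 - math.exp(-dt / self.tau)) * (x - self.y)
        return self.y


def lowpass_update(prev_output: float, value: float, dt: float,
                   cutoff_hz: float = 0.25) -> float:
    """Single step of the first-order low-pass (functional form)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = 1.0 / (2.0 * math.pi * cutoff_hz)
    return prev_output + (1.0 - math.exp(-dt / tau)) * (value - prev_output)


class MovingAverage:
    """Trailing arithmetic mean over a fixed time window (ring buffer)."""

    def __init__(self, window_s: float, dt: float,
                 initial: Optional[float] = None):
        if window_s <= 0 or dt <= 0:
            raise ValueError("window and dt must be positive")
        self.n = max(int(round(window_s / dt)), 1)
        self.buf: deque = deque(maxlen=self.n)
        self.total = 0.0
        if initial is not None:
            self.buf.extend([initial] * self.n)
            self.total = initial * self.n

    def update(self, x: float) -> float:
        if len(self.buf) == self.n:
            self.total -= self.buf[0]
        self.buf.append(x)
        self.total += x
        return self.total / len(self.buf)

    @property
    def value(self) -> float:
        return self.total / len(self.buf) if self.buf else 0.0


def sample_plved(lv_pressure: np.ndarray, beat_onsets: np.ndarray,
                 dt: float, current_time: Optional[float] = None) -> float:
    """Instantaneous PLVED (mmHg): LV pressure at the sample immediately
    preceding the most recent beat onset.

    The bench's automatic controller times the beats, so end-diastole is
    known exactly; the same convention applies here via the recorded
    beat-onset timestamps.
    """
    onsets = np.asarray(beat_onsets, dtype=float)
    n = len(lv_pressure)
    if n == 0:
        raise ValueError("empty LV pressure trace")
    if current_time is None:
        current_time = n * dt
    onsets = onsets[(onsets <= current_time) & (onsets > 0.0)]
    if len(onsets) == 0:
        raise ValueError("no completed beat before current_time")
    idx = int(round(onsets[-1] / dt)) - 1
    idx = min(max(idx, 0), n - 1)
    return float(lv_pressure[idx])


def sample_plved_series(lv_pressure: np.ndarray, beat_onsets: np.ndarray,
                        dt: float) -> tuple[np.ndarray, np.ndarray]:
    """PLVED sample per completed beat: (onset times, PLVED values)."""
    onsets = np.asarray(beat_onsets, dtype=float)
    onsets = onsets[onsets > 0.0]
    times, values = [], []
    n = len(lv_pressure)
    for t0 in onsets:
        idx = int(round(t0 / dt)) - 1
        if 0 <= idx < n:
            times.append(t0)
            values.append(float(lv_pressure[idx]))
    return np.asarray(times), np.asarray(values)


def csc_command(set_speed: float = 2100.0, min_speed: float = 1800.0) -> float:
    """Constant-speed command, clamped at the minimum operational speed."""
    return max(set_speed, min_speed)


class ConstantSpeedController:
    """Constant speed controller (CSC): ignores hemodynamics entirely."""

    def __init__(self, set_speed: float = 2100.0, min_speed: float = 1800.0):
        self.set_speed = csc_command(set_speed, min_speed)
        self.initial_speed = self.set_speed

    def step(self, t: float, p_lv: float, q_pump: float, omega: float,
             new_beat: bool) -> float:
        return self.set_speed


class _PIDCore:
    """Shared PID machinery: filters, trapezoidal integrator, anti-windup."""

    def __init__(self, gains: PIDGains, min_speed: float, max_speed: float,
                 cutoff_hz: float = 0.25, mode: str = "incremental",
                 initial_speed: float = 2100.0, initial_flow: float = 5.2):
        if mode not in ("incremental", "absolute"):
            raise ValueError("mode must be 'incremental' or 'absolute'")
        self.gains = gains
        self.min_speed = min_speed
        self.max_speed = max_speed
        self.mode = mode
        self.initial_speed = initial_speed
        self.lp_flow = LowPassFilter(cutoff_hz, initial=initial_flow)
        self.lp_speed = LowPassFilter(cutoff_hz, initial=initial_speed)
        self.lp_err = LowPassFilter(cutoff_hz, initial=0.0)
        self.integral = 0.0
        self.prev_err = 0.0
        self.prev_err_f = 0.0
        self.command = initial_speed

    def update(self, reference: float, q_pump: float, omega: float) -> float:
        g = self.gains
        dt = g.period
        qbar = self.lp_flow.update(q_pump, dt)
        wbar = self.lp_speed.update(omega, dt)
        err = reference - qbar
        err_f = self.lp_err.update(err, dt)
        # trapezoidal integral, derivative on the filtered error
        new_integral = self.integral + 0.5 * g.ki * (err + self.prev_err) * dt
        deriv = (err_f - self.prev_err_f) / dt
        base = wbar if self.mode == "incremental" else self.initial_speed
        u = base + g.kp * err + new_integral + g.kd * deriv
        if u > self.max_speed:
            cmd = self.max_speed
            if new_integral <= self.integral:   # still allow unwinding
                self.integral = new_integral
        elif u < self.min_speed:
            cmd = self.min_speed
            if new_integral >= self.integral:
                self.integral = new_integral
        else:
            cmd = u
            self.integral = new_integral
        self.prev_err = err
        self.prev_err_f = err_f
        self.command = cmd
        return cmd


class StarlingLikeController:
    """Preload-based Starling-like controller (SLC).

    Per 0.5 ms step: hold the per-beat PLVED sample, low-pass it to
    PLVED_m, evaluate the control line, smooth the reference with a 1 s
    moving average, and track it with the PID against the low-passed mean
    pump flow.  The commanded mean speed is clamped to
    [min_speed, max_speed].
    """

    def __init__(self, line: Optional[ControlLine] = None,
                 gains: Optional[PIDGains] = None,
                 min_speed: float = 1800.0, max_speed: float = 3000.0,
                 cutoff_hz: float = 0.25, ma_window_s: float = 1.0,
                 mode: str = "incremental",
                 initial_speed: float = 2100.0,
                 initial_plved: float = 7.5):
        self.line = line if line is not None else ControlLine()
        self.gains = gains if gains is not None else PIDGains()
        q0 = control_line_eval(initial_plved, self.line)
        self.pid = _PIDCore(self.gains, min_speed, max_speed, cutoff_hz,
                            mode, initial_speed, initial_flow=q0)
        self.lp_plved = LowPassFilter(cutoff_hz, initial=initial_plved)
        self.ma_ref = MovingAverage(ma_window_s, self.gains.period,
                                    initial=q0)
        self.initial_speed = initial_speed
        self._plved_raw = initial_plved
        self._prev_p_lv = initial_plved
        self.plved_m = initial_plved
        self.reference = q0
        self.plved_samples: list[tuple[float, float]] = []

    def step(self, t: float, p_lv: float, q_pump: float, omega: float,
             new_beat: bool) -> float:
        if new_beat and t > 0.0:
            self._plved_raw = self._prev_p_lv
            self.plved_samples.append((t, self._plved_raw))
        self._prev_p_lv = p_lv
        dt = self.gains.period
        self.plved_m = self.lp_plved.update(self._plved_raw, dt)
        q_raw = control_line_eval(self.plved_m, self.line)
        self.reference = self.ma_ref.update(q_raw)
        return self.pid.update(self.reference, q_pump, omega)

    # optional debug channels recorded by the integrator
    def internals(self) -> tuple[str, ...]:
        return ("plved_m", "ref_flow", "qbar")

    def internal_value(self, name: str) -> float:
        if name == "plved_m":
            return self.plved_m
        if name == "ref_flow":
            return self.reference
        if name == "qbar":
            return self.pid.lp_flow.y
        raise KeyError(name)


class FlowTrackingController:
    """PID flow tracking against an externally supplied reference.

    Used for the controller tuning experiment: a step in the mean-flow
    set point (1.80 -> 5.2 L/min) while the same filter bank and PID act
    on the plant.  ``reference`` is a callable t -> L/min.
    """

    def __init__(self, reference: Callable[[float], float],
                 gains: Optional[PIDGains] = None,
                 min_speed: float = 1800.0, max_speed: float = 3000.0,
                 cutoff_hz: float = 0.25, ma_window_s: float = 1.0,
                 mode: str = "incremental",
                 initial_speed: float = 1800.0):
        self.gains = gains if gains is not None else PIDGains()
        q0 = reference(0.0)
        self.reference_fn = reference
        self.pid = _PIDCore(self.gains, min_speed, max_speed, cutoff_hz,
                            mode, initial_speed, initial_flow=q0)
        self.ma_ref = MovingAverage(ma_window_s, self.gains.period,
                                    initial=q0)
        self.initial_speed = initial_speed
        self.reference = q0

    def step(self, t: float, p_lv: float, q_pump: float, omega: float,
             new_beat: bool) -> float:
        self.reference = self.ma_ref.update(self.reference_fn(t))
        return self.pid.update(self.reference, q_pump, omega)

    def internals(self) -> tuple[str, ...]:
        return ("ref_flow", "qbar")

    def internal_value(self, name: str) -> float:
        if name == "ref_flow":
            return self.reference
        if name == "qbar":
            return self.pid.lp_flow.y
        raise KeyError(name)
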