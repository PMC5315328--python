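"""Deterministic synthetic hemodynamic traces for controller/metric tests.

These fixtures emulate the loop's 2 kHz sensor streams without running
the plant: each channel is a mean level plus a half-sinusoid systolic
pulse train at the configured heart rate plus seeded Gaussian noise.
The generator supports injecting a known per-beat PLVED sequence (for
round-trip tests of the preload sampler) and scripted limit excursions
(for hand-checkable RMSHD values).  Identical spec + seed always yields
identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .plant import TRACE_CHANNELS, HemodynamicTrace

__all__ = ["FixtureSpec", "Excursion", "generate_trace",
           "generate_step_reference"]

#: default channel means (pressures mmHg, flows L/min, speed rpm)
DEFAULT_MEANS = {
    "p_la": 10.0, "p_lv": 8.0, "p_sa": 90.0, "p_ra": 5.0, "p_rv": 5.0,
    "p_pa": 16.0, "q_sys": 5.2, "q_pulm": 5.2, "q_pump": 5.2,
    "speed_rpm": 2100.0,
}
#: default pulse amplitudes (same units as the channel)
DEFAULT_AMPLITUDES = {
    "p_la": 2.0, "p_lv": 25.0, "p_sa": 8.0, "p_ra": 1.5, "p_rv": 12.0,
    "p_pa": 4.0, "q_sys": 1.0, "q_pulm": 1.0, "q_pump": 0.8,
    "speed_rpm": 0.0,
}


@dataclass(frozen=True)
class Excursion:
    """Scripted override of one channel to a fixed value over a window."""

    channel: str
    value: float
    start: float
    duration: float


@dataclass
class FixtureSpec:
    """Specification of a synthetic trace."""

    duration: float = 30.0          # s
    sample_rate: float = 2000.0     # Hz
    heart_rate: float = 60.0        # bpm
    systolic_fraction: float = 0.35
    noise_sd_pressure: float = 0.5  # mmHg
    noise_sd_flow: float = 0.05     # L/min
    seed: int = 0
    means: dict = field(default_factory=dict)
    amplitudes: dict = field(default_factory=dict)
    plved_sequence: Optional[Sequence[float]] = None
    excursions: tuple[Excursion, ...] = ()

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def generate_trace(spec: FixtureSpec) -> HemodynamicTrace:
    """Generate a pulsatile multichannel trace from a spec.

    The LV pressure channel is built beat-by-beat: a half-sinusoid
    systolic pulse riding on the beat's diastolic level, which equals the
    injected PLVED sequence value when one is supplied (so the sample
    just before the *next* beat onset recovers it exactly).
    """
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration / dt))
    period = 60.0 / spec.heart_rate
    t = np.arange(n) * dt
    phase = np.mod(t, period)
    beat_index = np.floor(t / period).astype(int)
    t_sys = spec.systolic_fraction * period
    pulse = np.where(phase < t_sys,
                     np.sin(np.pi * np.minimum(phase, t_sys) / t_sys), 0.0)
    onsets = np.arange(0.0, spec.duration - 0.5 * dt, period)

    rng = np.random.default_rng(spec.seed)
    means = dict(DEFAULT_MEANS, **spec.means)
    amps = dict(DEFAULT_AMPLITUDES, **spec.amplitudes)
    channels: dict[str, np.ndarray] = {}
    for name in TRACE_CHANNELS:
        if name == "p_lv" and spec.plved_sequence is not None:
            seq = np.asarray(spec.plved_sequence, dtype=float)
            base = seq[np.minimum(beat_index, len(seq) - 1)]
        else:
            base = np.full(n, means[name])
        sd = (spec.noise_sd_flow if name.startswith("q_")
              else 0.0 if name == "speed_rpm" else spec.noise_sd_pressure)
        noise = rng.normal(0.0, sd, n) if sd > 0 else 0.0
        channels[name] = base + amps[name] * pulse + noise
    for exc in spec.excursions:
        if exc.channel not in channels:
            raise KeyError(f"unknown channel {exc.channel!r}")
        i0 = max(int(round(exc.start / dt)), 0)
        i1 = min(int(round((exc.start + exc.duration) / dt)), n)
        channels[exc.channel][i0:i1] = exc.value
    return HemodynamicTrace(dt=dt, channels=channels,
                            beat_onsets=onsets,
                            meta={"fixture": True, "seed": spec.seed})


def generate_step_reference(initial: float, final: float, step_time: float,
                            duration: Optional[float] = None):
    """Piecewise-constant reference signal r(t): ``initial`` before
    ``step_time``, ``final`` after.

    Returns a callable; used for the PID tuning experiment (a step in
    the mean pump-flow set point).
    """
    if duration is not None and not 0.0 <= step_time <= duration:
        raise ValueError("step_time must lie within the duration")

    def reference(t: float) -> float:
        return final if t >= step_time else initial

    return reference
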