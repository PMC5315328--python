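"""Clinical-acceptability scoring and summary statistics.

The root mean squared hemodynamic deviation (RMSHD) quantifies how far a
controller lets the key hemodynamic variables stray outside predefined
clinical limits over an evaluation epoch of length Td:

    v_x(t)   = max(y_x(t) - UL_x, LL_x - y_x(t), 0)          (excursion)
    NSD_x(t) = ( v_x(t) / ((LL_x + UL_x)/2) )^2              (normalised)
    SHD_x    = integral_0^Td NSD_x(t) dt                     (trapezoid)
    RMSHD    = 100 * sqrt( (1/Td) * sum_x SHD_x )            (%)

over x in {MAP, PLVED, CO}.  RMSHD is zero exactly when every variable
stays inside its limits for the whole epoch.  The cardiac-output limits
are scenario dependent: [4, 6] L/min at rest and during hemorrhage,
[6, 11] L/min during exercise.

Mean signals for scoring and for the summary tables are obtained with
the same 0.25 Hz first-order low-pass used by the controller's feedback
path, initialised at the first sample so that constant inputs score
exactly; PLVED is sampled beat-wise and held between beats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .controllers import sample_plved_series
from .plant import HemodynamicTrace

__all__ = [
    "VariableLimits", "HemodynamicLimits", "RMSHDResult", "TraceSummary",
    "nsd", "shd", "rmshd", "mean_signal", "plved_signal",
    "evaluate_trace", "summarize", "percent_change", "detect_suction",
]


@dataclass(frozen=True)
class VariableLimits:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower limit must be below upper limit")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class HemodynamicLimits:
    """Safe operating bounds for MAP, PLVED and cardiac output."""

    map: VariableLimits = field(
        default_factory=lambda: VariableLimits(80.0, 120.0))
    plved: VariableLimits = field(
        default_factory=lambda: VariableLimits(2.0, 15.0))
    co: VariableLimits = field(
        default_factory=lambda: VariableLimits(4.0, 6.0))

    @classmethod
    def for_scenario(cls, scenario: str) -> "HemodynamicLimits":
        """Scenario-dependent limits: exercise widens the CO band."""
        if scenario == "exercise":
            return cls(co=VariableLimits(6.0, 11.0))
        return cls()


def nsd(value: float | np.ndarray, lower: float,
        upper: float) -> float | np.ndarray:
    """Normalised squared deviation of ``value`` outside [lower, upper]."""
    if not lower < upper:
        raise ValueError("degenerate limits")
    v = np.maximum(np.maximum(value - upper, lower - value), 0.0)
    mid = 0.5 * (lower + upper)
    out = (v / mid) ** 2
    return float(out) if np.isscalar(value) else out


def shd(nsd_series: np.ndarray, dt: float) -> float:
    """Squared hemodynamic deviation: trapezoidal integral of NSD."""
    arr = np.asarray(nsd_series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty NSD series")
    if arr.size == 1:
        return 0.0
    return float(np.trapezoid(arr, dx=dt))


def rmshd(map_series: np.ndarray, plved_series: np.ndarray,
          co_series: np.ndarray, limits: HemodynamicLimits,
          dt: float) -> "RMSHDResult":
    """Aggregate RMSHD (%) over equal-length mean-signal series."""
    n = len(map_series)
    if not (len(plved_series) == n and len(co_series) == n):
        raise ValueError("series lengths differ")
    td = (n - 1) * dt
    if td <= 0:
        raise ValueError("evaluation duration must be positive")
    shd_map = shd(nsd(np.asarray(map_series), limits.map.lower,
                      limits.map.upper), dt)
    shd_plved = shd(nsd(np.asarray(plved_series), limits.plved.lower,
                        limits.plved.upper), dt)
    shd_co = shd(nsd(np.asarray(co_series), limits.co.lower,
                     limits.co.upper), dt)
    value = 100.0 * math.sqrt((shd_map + shd_plved + shd_co) / td)
    return RMSHDResult(shd_map=shd_map, shd_plved=shd_plved, shd_co=shd_co,
                       td=td, rmshd=value)


@dataclass
class RMSHDResult:
    """Per-variable deviation integrals and the aggregate percentage."""

    shd_map: float
    shd_plved: float
    shd_co: float
    td: float
    rmshd: float

    def as_dict(self) -> dict:
        return {"SHD_MAP": self.shd_map, "SHD_PLVED": self.shd_plved,
                "SHD_CO": self.shd_co, "Td_s": self.td,
                "RMSHD_percent": self.rmshd}


# ---------------------------------------------------------------------------
# Mean-signal extraction from traces
# ---------------------------------------------------------------------------

def mean_signal(series: np.ndarray, dt: float,
                cutoff_hz: float = 0.25) -> np.ndarray:
    """0.25 Hz first-order low-pass of a pulsatile channel.

    Initialised at the first sample (unit DC gain), so a constant input
    is returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x
    b = 1.0 - math.exp(-dt * 2.0 * math.pi * cutoff_hz)
    zi = np.array([(1.0 - b) * x[0]])
    y, _ = _signal.lfilter([b], [1.0, b - 1.0], x, zi=zi)
    return y


def plved_signal(trace: HemodynamicTrace,
                 cutoff_hz: float = 0.25) -> np.ndarray:
    """Beat-wise PLVED held between beats, then low-pass filtered.

    Mirrors the controller's preload feedback path so that offline
    scoring sees the same PLVED_m the controller acted on.
    """
    times, values = sample_plved_series(trace["p_lv"], trace.beat_onsets,
                                        trace.dt)
    n = len(trace)
    held = np.empty(n)
    if len(values) == 0:
        held[:] = trace["p_lv"][0] if n else 0.0
        return held
    idx = np.minimum((times / trace.dt).round().astype(int), n)
    held[: idx[0]] = values[0]
    for k in range(len(values)):
        stop = idx[k + 1] if k + 1 < len(values) else n
        held[idx[k]: stop] = values[k]
    return mean_signal(held, trace.dt, cutoff_hz)


def evaluate_trace(trace: HemodynamicTrace, limits: HemodynamicLimits,
                   t_start: Optional[float] = None,
                   t_end: Optional[float] = None) -> RMSHDResult:
    """Score a trace over [t_start, t_end) (default: the whole trace).

    Mean signals (MAP from p_sa, CO from the systemic flow, PLVED_m from
    beat-wise samples) are computed over the full trace so the filters
    carry realistic history into the epoch, then scored over the window.
    """
    dt = trace.dt
    map_m = mean_signal(trace["p_sa"], dt)
    co_m = mean_signal(trace["q_sys"], dt)
    plved_m = plved_signal(trace)
    i0 = 0 if t_start is None else max(int(round(t_start / dt)), 0)
    i1 = len(trace) if t_end is None else min(int(round(t_end / dt)),
                                              len(trace))
    return rmshd(map_m[i0:i1], plved_m[i0:i1], co_m[i0:i1], limits, dt)


# ---------------------------------------------------------------------------
# Steady-state summaries
# ---------------------------------------------------------------------------

@dataclass
class TraceSummary:
    """Mean +/- sd of the reported variables over an averaging window."""

    speed_rpm: tuple[float, float]
    map_mmhg: tuple[float, float]
    pla_mmhg: tuple[float, float]
    plved_mmhg: tuple[float, float]
    co_lpm: tuple[float, float]
    qp_lpm: tuple[float, float]
    window_s: float

    def as_dict(self) -> dict:
        def pair(p):
            return {"mean": p[0], "sd": p[1]}
        return {
            "speed_rpm": pair(self.speed_rpm),
            "MAP_mmHg": pair(self.map_mmhg),
            "PLA_mmHg": pair(self.pla_mmhg),
            "PLVED_mmHg": pair(self.plved_mmhg),
            "CO_L_min": pair(self.co_lpm),
            "QP_L_min": pair(self.qp_lpm),
            "window_s": self.window_s,
        }


def summarize(trace: HemodynamicTrace, window: float = 30.0) -> TraceSummary:
    """Per-channel mean and sd over the trailing ``window`` seconds.

    PLVED is summarised over its beat-wise samples within the window (a
    per-beat quantity has no meaning at the raw sample rate).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if window > trace.duration + 1e-9:
        raise ValueError("window longer than trace")
    i0 = len(trace) - int(round(window / trace.dt))
    i0 = max(i0, 0)

    def stats(x: np.ndarray) -> tuple[float, float]:
        return float(np.mean(x)), float(np.std(x))

    t0 = i0 * trace.dt
    times, plved = sample_plved_series(trace["p_lv"], trace.beat_onsets,
                                       trace.dt)
    in_win = times >= t0
    plved_stats = stats(plved[in_win]) if np.any(in_win) else (
        float("nan"), float("nan"))
    return TraceSummary(
        speed_rpm=stats(trace["speed_rpm"][i0:]),
        map_mmhg=stats(mean_signal(trace["p_sa"], trace.dt)[i0:]),
        pla_mmhg=stats(trace["p_la"][i0:]),
        plved_mmhg=plved_stats,
        co_lpm=stats(trace["q_sys"][i0:]),
        qp_lpm=stats(trace["q_pump"][i0:]),
        window_s=window,
    )


def percent_change(reference: float, value: float) -> float:
    """(value - reference) / reference in percent; rejects a zero baseline."""
    if reference == 0:
        raise ZeroDivisionError("zero-mean reference for percent change")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# Suction detection
# ---------------------------------------------------------------------------

def detect_suction(trace: HemodynamicTrace,
                   window_beats: int = 5) -> tuple[bool, Optional[float]]:
    """Detect left-ventricular suction in a trace.

    Flags suction if the mean of PLVED over any ``window_beats``
    consecutive beats drops below 0 mmHg, or if the recorded LV volume
    reaches the collapse floor.  Returns (flag, first onset time or None).
    """
    times, plved = sample_plved_series(trace["p_lv"], trace.beat_onsets,
                                       trace.dt)
    onset: Optional[float] = None
    if len(plved) >= window_beats:
        kernel = np.ones(window_beats) / window_beats
        means = np.convolve(plved, kernel, mode="valid")
        hits = np.nonzero(means < 0.0)[0]
        if hits.size:
            onset = float(times[hits[0] + window_beats - 1])
    if "v_lv" in trace.channels and len(trace):
        floor = trace.meta.get("collapse_floor")
        if floor is not None:
            low = np.nonzero(trace["v_lv"] <= floor)[0]
            if low.size:
                t_low = float(low[0] * trace.dt)
                onset = t_low if onset is None else min(onset, t_low)
    return onset is not None, onset
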