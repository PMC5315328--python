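"""Lumped-parameter surrogate of a dual-circuit mock circulation loop (MCL).

The loop is the bench apparatus used to evaluate physiological controllers
for rotary left-ventricular assist devices (LVADs): two pneumatically driven
ventricles with a built-in Starling mechanism, two passively filling atria,
four Windkessel chambers (systemic/pulmonary, arterial/venous), adjustable
systemic and pulmonary vascular resistances, and four mechanical check
valves.  This module replaces the hardware with a deterministic ODE model:

    LA -> MV -> LV -> AoV -> SAC -> SVR -> SVC -> RA
       -> TV -> RV -> PuV -> PAC -> PVR -> PVC -> LA

with the assist pump drawing from the LV and returning to the systemic
arterial chamber.  Ventricles are time-varying elastance chambers

    P(V, t) = e(t) * E_es * (V - V0) + (1 - e(t)) * P_ed(V)

where e(t) is a sin^2 activation over the systolic interval and P_ed is a
soft-exponential end-diastolic pressure-volume relation, so the left
ventricular end-diastolic pressure (PLVED) is well defined and may go
negative when the pump over-drains the ventricle.  Beat-to-beat Starling
responsiveness is modelled by scaling each ventricle's end-systolic
elastance with its end-diastolic pressure sampled at beat onset.

Units: pressures mmHg, volumes mL, time s; flows mL/s internally, reported
in L/min.  Vascular resistances are configured in dyne.s.cm^-5 and converted
internally (divide by 1333.22 to obtain mmHg.s/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pump import PumpParameters
    from .scenarios import ScenarioSchedule

__all__ = [
    "DYNE_PER_MMHG_S_ML",
    "lv_edpvr",
    "rv_edpvr",
    "MLPS_PER_LPM",
    "CVSParameters",
    "CVSState",
    "HemodynamicTrace",
    "elastance_driver",
    "starling_elastance",
    "contractility_to_elastance",
    "valve_flow",
    "compute_pressures",
    "derivatives",
    "fluid_shift_flow",
    "mean_filling_pressure",
    "equilibrium_state",
    "initial_state",
    "integrate",
]

#: dyne.s.cm^-5 per mmHg.s/mL
DYNE_PER_MMHG_S_ML = 1333.22
#: mL/s per L/min
MLPS_PER_LPM = 1000.0 / 60.0

# Channel order of the recorded trace (CSV column order after time_s).
TRACE_CHANNELS = (
    "p_la", "p_lv", "p_sa", "p_ra", "p_rv", "p_pa",
    "q_sys", "q_pulm", "q_pump", "speed_rpm",
)
# Extra diagnostic channels always recorded alongside the standard ones.
EXTRA_CHANNELS = ("v_lv",)


def dyne_to_mmhg_s_per_ml(r_dyne: float) -> float:
    """Convert a vascular resistance from dyne.s.cm^-5 to mmHg.s/mL."""
    return r_dyne / DYNE_PER_MMHG_S_ML


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------

@dataclass
class CVSParameters:
    """Parameters of the lumped circulation.

    The defaults are the tuned configuration: with the constant-speed
    controller at 2100 rpm under the baseline heart-failure condition
    (HR 60 bpm, SVR 1300 dyne.s.cm^-5, PVR 110 dyne.s.cm^-5,
    contractility index 1040 mmHg/s) the loop settles near a mean pump
    flow of 5.2 L/min, mean arterial pressure of ~90 mmHg and a mean
    left-ventricular end-diastolic pressure of ~7-9 mmHg.
    """

    # Timing
    heart_rate: float = 60.0           # bpm
    systolic_fraction: float = 0.35    # fraction of the cycle in systole

    # Vascular resistances (configured in dyne.s.cm^-5, as on the bench)
    svr_dyne: float = 1300.0
    pvr_dyne: float = 110.0

    # Windkessel chamber compliances (mL/mmHg)
    c_sa: float = 1.3     # systemic arterial
    c_sv: float = 66.0    # systemic venous
    c_pa: float = 2.8     # pulmonary arterial
    c_pv: float = 12.0    # pulmonary venous
    # Atrial compliances (mL/mmHg)
    c_la: float = 6.0
    c_ra: float = 10.0

    # Check valve and connecting resistances (mmHg.s/mL)
    r_mv: float = 0.02    # mitral
    r_av: float = 0.025   # aortic
    r_tv: float = 0.02    # tricuspid
    r_pv: float = 0.02    # pulmonary valve
    r_sv_ra: float = 0.025   # systemic venous chamber -> right atrium
    r_pv_la: float = 0.012   # pulmonary venous chamber -> left atrium

    # Left ventricle.  The passive (end-diastolic) pressure follows a
    # concave-logarithmic P-V relation, P_ed = c * ln(1 + (V-V0)/s): the
    # sac is stiff when under-filled (pressure falls steeply toward the
    # collapse range below V0) and increasingly compliant once distended.
    lv_v0: float = 10.0          # unstressed volume, mL
    lv_edp_c: float = 6.0        # EDPVR pressure scale, mmHg
    lv_edp_s: float = 25.0       # EDPVR volume scale, mL
    # Contractility index C_lv (mmHg/s) and its affine map to end-systolic
    # elastance E_es = clamp(slope * C_lv + intercept, floor, ...).
    c_lv: float = 1040.0
    clv_slope: float = 7.7e-4    # (mmHg/mL) per (mmHg/s)
    clv_intercept: float = -0.35
    ees_floor: float = 0.02      # mmHg/mL

    # Right ventricle.  Its passive (end-diastolic) pressure saturates at
    # a ceiling: P_ed = a * (1 - exp(-b*(V - V0))), so a disabled right
    # ventricle cannot passively force flow against a raised pulmonary
    # resistance by dilating without bound.
    rv_v0: float = 20.0
    rv_edp_a: float = 15.0       # passive pressure ceiling, mmHg
    rv_edp_b: float = 0.0015     # 1/mL
    rv_ees: float = 0.70         # mmHg/mL

    # Built-in ventricular Starling mechanism: multiplicative elastance
    # factor clamp(1 + gain*(EDP - ref), lo, hi), updated each beat.
    lv_starling_gain: float = 0.15   # 1/mmHg
    lv_starling_ref: float = 7.5     # mmHg
    lv_starling_min: float = 0.2
    lv_starling_max: float = 2.2
    rv_starling_gain: float = 0.8
    rv_starling_ref: float = 5.5
    rv_starling_min: float = 0.02
    rv_starling_max: float = 1.25

    # Atrial / ventricular unstressed volumes of passive chambers (mL)
    la_v0: float = 5.0
    ra_v0: float = 5.0
    sa_v0: float = 50.0
    sv_v0: float = 150.0
    pa_v0: float = 20.0
    pv_v0: float = 30.0

    # Reservoir (systemic venous compliance chamber head space) volume, mL
    reservoir_volume: float = 800.0

    # Ventricular collapse (suction) guard: below v_floor the pump inlet
    # resistance rises steeply, floor-limiting LV volume.
    lv_collapse_floor: float = 7.5    # mL
    lv_collapse_width: float = 0.4    # mL
    lv_collapse_res: float = 300.0    # mmHg/(L/min) added at full collapse

    def __post_init__(self) -> None:
        for name in ("c_sa", "c_sv", "c_pa", "c_pv", "c_la", "c_ra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"compliance {name} must be > 0")
        for name in ("svr_dyne", "pvr_dyne", "r_mv", "r_av", "r_tv", "r_pv",
                     "r_sv_ra", "r_pv_la"):
            if getattr(self, name) < 0:
                raise ValueError(f"resistance {name} must be >= 0")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be > 0")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic fraction must lie in (0, 1)")

    # Derived quantities -------------------------------------------------
    @property
    def svr(self) -> float:
        """Systemic vascular resistance in mmHg.s/mL."""
        return dyne_to_mmhg_s_per_ml(self.svr_dyne)

    @property
    def pvr(self) -> float:
        """Pulmonary vascular resistance in mmHg.s/mL."""
        return dyne_to_mmhg_s_per_ml(self.pvr_dyne)

    @property
    def period(self) -> float:
        """Cardiac cycle length, s."""
        return 60.0 / self.heart_rate

    @property
    def lv_ees(self) -> float:
        """Baseline LV end-systolic elastance mapped from C_lv, mmHg/mL."""
        return contractility_to_elastance(
            self.c_lv, self.clv_slope, self.clv_intercept, self.ees_floor)


_STATE_FIELDS = ("v_la", "v_lv", "v_sa", "v_sv", "v_ra", "v_rv",
                 "v_pa", "v_pv", "v_reservoir", "q_pump")


@dataclass
class CVSState:
    """Instantaneous state of the loop.

    Volumes in mL; ``q_pump`` is the pump flow in L/min (it is a dynamic
    state because the cannulae carry inertance).  ``phase`` is the time
    since the current beat's onset; the per-beat effective elastances are
    refreshed at each beat onset from the sampled end-diastolic pressures.
    """

    v_la: float
    v_lv: float
    v_sa: float
    v_sv: float
    v_ra: float
    v_rv: float
    v_pa: float
    v_pv: float
    v_reservoir: float
    q_pump: float = 0.0        # L/min
    phase: float = 0.0         # s since beat onset
    lv_ees_eff: float = 0.0    # effective elastances for the current beat
    rv_ees_eff: float = 0.0
    shifted_volume: float = 0.0  # cumulative scripted shift into circuit, mL

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS])

    @property
    def circuit_volume(self) -> float:
        """Total fluid volume in the circulation (excl. reservoir), mL."""
        return (self.v_la + self.v_lv + self.v_sa + self.v_sv
                + self.v_ra + self.v_rv + self.v_pa + self.v_pv)


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

def elastance_driver(phase: float, heart_rate: float,
                     systolic_fraction: float) -> float:
    """Normalised activation e(t) in [0, 1] for the ventricular driver.

    A shifted sin^2 pulse over the systolic interval: zero at beat onset,
    a single maximum of 1 at mid-systole, and zero throughout diastole.
    """
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    period = 60.0 / heart_rate
    t_sys = systolic_fraction * period
    if phase < 0 or phase >= period:
        phase = phase % period
    if phase >= t_sys:
        return 0.0
    s = math.sin(math.pi * phase / t_sys)
    return s * s


def contractility_to_elastance(c_lv: float, slope: float, intercept: float,
                               floor: float) -> float:
    """Affine map from the bench contractility index C_lv (mmHg/s) to an
    end-systolic elastance (mmHg/mL), floored to stay positive.

    The bench reports contractility as a peak dP/dt-like index; the lumped
    model needs an elastance.  The affine coefficients are part of the
    tuned configuration; the floor makes the "contractility eliminated"
    setting (C_lv = 25 mmHg/s) produce a nearly passive ventricle instead
    of a negative stiffness.
    """
    return max(slope * c_lv + intercept, floor)


def starling_elastance(preload: float, base_elastance: float, gain: float,
                       ref: float = 7.5, lo: float = 0.2,
                       hi: float = 3.0) -> float:
    """Effective end-systolic elastance after the ventricle's built-in
    Starling response.

    ``preload`` is the end-diastolic pressure sampled at beat onset (mmHg).
    The multiplier 1 + gain*(preload - ref) is clamped to [lo, hi], so the
    response is monotone in preload, anchored at the nominal baseline
    preload ``ref`` (where it returns ``base_elastance`` exactly) and
    saturates at a configured ceiling.
    """
    if base_elastance < 0:
        raise ValueError("base elastance must be non-negative")
    factor = 1.0 + gain * (preload - ref)
    factor = min(max(factor, lo), hi)
    return base_elastance * factor


def valve_flow(upstream: float, downstream: float, resistance: float) -> float:
    """Flow (mL/s) through an ideal check valve with series resistance.

    Forward flow (upstream - downstream)/R when the pressure gradient is
    positive; the valve closes (zero flow) otherwise.
    """
    if resistance <= 0:
        raise ValueError("valve resistance must be positive")
    dp = upstream - downstream
    return dp / resistance if dp > 0.0 else 0.0


def lv_edpvr(v: float, v0: float, c: float, s: float) -> float:
    """LV end-diastolic P-V relation, negative below V0 (suction range).

    Below 10% of the volume scale the logarithm is continued linearly
    (matching slope), keeping the relation defined for any volume the
    integrator may transiently visit.
    """
    arg = (v - v0) / s
    if arg > -0.9:
        return c * math.log1p(arg)
    return c * (math.log(0.1) + (arg + 0.9) * 10.0)


def lv_edpvr_inv(p: float, v0: float, c: float, s: float) -> float:
    return v0 + s * (math.exp(p / c) - 1.0)


def rv_edpvr(v: float, v0: float, a: float, b: float) -> float:
    """RV end-diastolic P-V relation: saturates at the ceiling ``a``."""
    return a * (1.0 - math.exp(-b * (v - v0)))


def rv_edpvr_inv(p: float, v0: float, a: float, b: float) -> float:
    if p >= a:
        raise ValueError("pressure above the RV passive ceiling")
    return v0 - math.log(1.0 - p / a) / b


def _ventricular_pressure(v: float, v0: float, act: float, ees_eff: float,
                          p_ed: float) -> float:
    """Time-varying elastance chamber pressure (mmHg)."""
    return act * ees_eff * (v - v0) + (1.0 - act) * p_ed


def compute_pressures(state: CVSState, params: CVSParameters,
                      act: float) -> dict[str, float]:
    """All chamber pressures (mmHg) at the given activation level."""
    p = params
    return {
        "p_la": (state.v_la - p.la_v0) / p.c_la,
        "p_ra": (state.v_ra - p.ra_v0) / p.c_ra,
        "p_sa": (state.v_sa - p.sa_v0) / p.c_sa,
        "p_sv": (state.v_sv - p.sv_v0) / p.c_sv,
        "p_pa": (state.v_pa - p.pa_v0) / p.c_pa,
        "p_pv": (state.v_pv - p.pv_v0) / p.c_pv,
        "p_lv": _ventricular_pressure(
            state.v_lv, p.lv_v0, act, state.lv_ees_eff or p.lv_ees,
            lv_edpvr(state.v_lv, p.lv_v0, p.lv_edp_c, p.lv_edp_s)),
        "p_rv": _ventricular_pressure(
            state.v_rv, p.rv_v0, act, state.rv_ees_eff or p.rv_ees,
            rv_edpvr(state.v_rv, p.rv_v0, p.rv_edp_a, p.rv_edp_b)),
    }


def derivatives(state: CVSState, params: CVSParameters, pump_flow: float,
                t: float, shift_flow: float = 0.0) -> np.ndarray:
    """Time derivative of the compartment volumes and the reservoir.

    ``pump_flow`` is in L/min (positive LV -> aorta); ``shift_flow`` is
    the scripted reservoir -> systemic-venous transfer in mL/s.  Returns
    d/dt of ``(v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv,
    v_reservoir, q_pump)`` with the pump-flow slot set to 0 (pump dynamics
    are owned by :mod:`slcsim.pump`).

    Reference implementation used by tests and by the equilibrium solver;
    :func:`integrate` uses an inlined, loop-optimised copy of the same
    mass balances.
    """
    vec = state.as_vector()
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite state passed to derivatives")
    if not math.isfinite(pump_flow):
        raise FloatingPointError("non-finite pump flow")
    p = params
    act = elastance_driver(state.phase, p.heart_rate, p.systolic_fraction)
    pr = compute_pressures(state, p, act)
    q_mv = valve_flow(pr["p_la"], pr["p_lv"], p.r_mv)
    q_av = valve_flow(pr["p_lv"], pr["p_sa"], p.r_av)
    q_tv = valve_flow(pr["p_ra"], pr["p_rv"], p.r_tv)
    q_puv = valve_flow(pr["p_rv"], pr["p_pa"], p.r_pv)
    q_sys = (pr["p_sa"] - pr["p_sv"]) / p.svr
    q_ret = (pr["p_sv"] - pr["p_ra"]) / p.r_sv_ra
    q_pulm = (pr["p_pa"] - pr["p_pv"]) / p.pvr
    q_pret = (pr["p_pv"] - pr["p_la"]) / p.r_pv_la
    q_p = pump_flow * MLPS_PER_LPM
    return np.array([
        q_pret - q_mv,                 # v_la
        q_mv - q_av - q_p,             # v_lv
        q_av + q_p - q_sys,            # v_sa
        q_sys - q_ret + shift_flow,    # v_sv
        q_ret - q_tv,                  # v_ra
        q_tv - q_puv,                  # v_rv
        q_puv - q_pulm,                # v_pa
        q_pulm - q_pret,               # v_pv
        -shift_flow,                   # v_reservoir
        0.0,                           # q_pump (owned by the pump model)
    ])


def fluid_shift_flow(volume_ml: float, duration_s: float, t_start: float,
                     t: float) -> float:
    """Scripted fluid-shift flow (mL/s) at time ``t``.

    A linear ramp moving exactly ``volume_ml`` from the reservoir into the
    systemic venous chamber (negative: circuit -> reservoir) over
    ``duration_s`` starting at ``t_start``.  Durations are capped at 20 s,
    matching how quickly the bench can complete a shift.
    """
    if duration_s <= 0 or duration_s > 20.0:
        raise ValueError("shift duration must lie in (0, 20] s")
    if t_start <= t < t_start + duration_s:
        return volume_ml / duration_s
    return 0.0


# ---------------------------------------------------------------------------
# Equilibrium / initialisation
# ---------------------------------------------------------------------------

def mean_filling_pressure(state: CVSState, params: CVSParameters) -> float:
    """Closed-form mean circulatory filling pressure (mmHg).

    With zero activation and zero pump flow the circulation relaxes to a
    single pressure P* = total stressed volume / total compliance, where
    ventricles contribute their nonlinear end-diastolic P-V relations.
    Solved by bracketed root finding on the total volume balance; used as
    an independent oracle for the ODE steady state.
    """
    from scipy.optimize import brentq

    p = params
    total = state.circuit_volume
    c_lin = p.c_la + p.c_ra + p.c_sa + p.c_sv + p.c_pa + p.c_pv
    v0_lin = (p.la_v0 + p.ra_v0 + p.sa_v0 + p.sv_v0 + p.pa_v0 + p.pv_v0)

    def excess_volume(pstar: float) -> float:
        v_lv = lv_edpvr_inv(pstar, p.lv_v0, p.lv_edp_c, p.lv_edp_s)
        v_rv = rv_edpvr_inv(min(pstar, 0.999 * p.rv_edp_a), p.rv_v0,
                            p.rv_edp_a, p.rv_edp_b)
        return c_lin * pstar + v0_lin + v_lv + v_rv - total

    return float(brentq(excess_volume, -20.0, 0.998 * p.rv_edp_a,
                        xtol=1e-10))


def initial_state(params: CVSParameters,
                  pressures: Optional[dict[str, float]] = None,
                  reservoir: Optional[float] = None) -> CVSState:
    """Build a starting state from target chamber pressures.

    The default pressures approximate the settled baseline heart-failure
    operating point so that the 120 s pre-transition epoch is spent
    refining, not finding, the steady state.
    """
    p = params
    pr = {
        "p_la": 9.5, "p_lv": 7.4, "p_sa": 90.0, "p_sv": 7.55,
        "p_ra": 5.0, "p_rv": 5.0, "p_pa": 16.0, "p_pv": 10.0,
    }
    if pressures:
        pr.update(pressures)

    st = CVSState(
        v_la=p.la_v0 + p.c_la * pr["p_la"],
        v_lv=lv_edpvr_inv(pr["p_lv"], p.lv_v0, p.lv_edp_c, p.lv_edp_s),
        v_sa=p.sa_v0 + p.c_sa * pr["p_sa"],
        v_sv=p.sv_v0 + p.c_sv * pr["p_sv"],
        v_ra=p.ra_v0 + p.c_ra * pr["p_ra"],
        v_rv=rv_edpvr_inv(pr["p_rv"], p.rv_v0, p.rv_edp_a, p.rv_edp_b),
        v_pa=p.pa_v0 + p.c_pa * pr["p_pa"],
        v_pv=p.pv_v0 + p.c_pv * pr["p_pv"],
        v_reservoir=p.reservoir_volume if reservoir is None else reservoir,
    )
    st.lv_ees_eff = starling_elastance(
        pr["p_lv"], p.lv_ees, p.lv_starling_gain, p.lv_starling_ref,
        p.lv_starling_min, p.lv_starling_max)
    st.rv_ees_eff = starling_elastance(
        pr["p_rv"], p.rv_ees, p.rv_starling_gain, p.rv_starling_ref,
        p.rv_starling_min, p.rv_starling_max)
    return st


def equilibrium_state(params: CVSParameters, duration: float = 600.0,
                      dt: float = 5e-3) -> CVSState:
    """Relax the passive circulation (no beats, no pump) to equilibrium.

    Integrates the volume ODEs with zero activation and zero pump flow;
    the result should match :func:`mean_filling_pressure` and is used as
    a numerical cross-check of the plant's mass balances.
    """
    zero_act = replace(params, c_lv=0.0, clv_intercept=0.0, clv_slope=0.0,
                       ees_floor=0.0)
    st = initial_state(zero_act)
    st.lv_ees_eff = 0.0
    st.rv_ees_eff = 0.0
    n = int(round(duration / dt))
    y = st.as_vector()
    for _ in range(n):
        k1 = _passive_deriv(y, zero_act)
        k2 = _passive_deriv(y + 0.5 * dt * k1, zero_act)
        k3 = _passive_deriv(y + 0.5 * dt * k2, zero_act)
        k4 = _passive_deriv(y + dt * k3, zero_act)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    for name, val in zip(_STATE_FIELDS, y):
        setattr(st, name, float(val))
    st.phase = 0.0
    return st


def _passive_deriv(y: np.ndarray, p: CVSParameters) -> np.ndarray:
    """Volume derivatives with zero activation and zero pump flow."""
    st = CVSState(*[float(v) for v in y])
    st.lv_ees_eff = 0.0
    st.rv_ees_eff = 0.0
    # valves pass both ways here?  No: keep diodes; equilibrium is reached
    # because all pressures equalise through the forward path.
    return derivatives(st, p, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------

@dataclass
class HemodynamicTrace:
    """Uniformly sampled multichannel hemodynamic recording.

    Pressures in mmHg, flows in L/min, speed in rpm.  ``beat_onsets``
    holds the times (s) at which a new cardiac cycle began.
    """

    dt: float
    channels: dict[str, np.ndarray]
    beat_onsets: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("sample period must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")

    def __len__(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    def __getitem__(self, key: str) -> np.ndarray:
        return self.channels[key]

    def window(self, t_start: float, t_end: float) -> "HemodynamicTrace":
        """Sub-trace covering [t_start, t_end)."""
        i0 = max(int(round(t_start / self.dt)), 0)
        i1 = min(int(round(t_end / self.dt)), len(self))
        onsets = self.beat_onsets
        onsets = onsets[(onsets >= t_start) & (onsets < t_end)]
        return HemodynamicTrace(
            dt=self.dt,
            channels={k: v[i0:i1] for k, v in self.channels.items()},
            beat_onsets=onsets - t_start,
            meta=dict(self.meta, window=(t_start, t_end)),
        )

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_s": self.time}
        for name in TRACE_CHANNELS:
            if name in self.channels:
                cols[name] = self.channels[name]
        for name in self.channels:
            if name not in cols:
                cols[name] = self.channels[name]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Main integrator
# ---------------------------------------------------------------------------

def integrate(state: CVSState, params: CVSParameters, controller,
              pump_params: "PumpParameters",
              schedule: Optional["ScenarioSchedule"] = None,
              duration: float = 240.0, dt: float = 5e-4,
              record_internals: bool = False) -> HemodynamicTrace:
    """Run the closed loop: plant + pump + controller (+ scenario schedule).

    Fixed-step RK4 at ``dt`` (default 0.5 ms, the controller sample
    period: the controller is invoked once per step).  The scenario
    schedule switches the plant parameters instantaneously at its
    transition time and drives the scripted fluid shift; beat onsets are
    recorded and the ventricles' effective elastances are refreshed at
    each onset from the sampled end-diastolic pressures (the loop's own
    Starling mechanism).

    Raises ``FloatingPointError`` if the state becomes non-finite.
    """
    if dt > 5e-4 + 1e-12:
        raise ValueError("dt must be <= 0.5 ms (controller sample period)")
    if duration < 0:
        raise ValueError("duration must be non-negative")

    n_steps = int(round(duration / dt))
    if n_steps == 0:
        return HemodynamicTrace(
            dt=dt,
            channels={name: np.empty(0)
                      for name in TRACE_CHANNELS + EXTRA_CHANNELS},
            beat_onsets=np.empty(0),
            meta={"duration": 0.0},
        )
    out = {name: np.empty(n_steps) for name in TRACE_CHANNELS + EXTRA_CHANNELS}
    if record_internals and hasattr(controller, "internals"):
        internal_names = tuple(controller.internals())
        for name in internal_names:
            out[name] = np.empty(n_steps)
    else:
        internal_names = ()
    beat_onsets = [0.0]

    pp = pump_params
    # Local bindings (hot loop)
    a0, a1, a2 = pp.a0, pp.a1, pp.a2
    r_can, l_can = pp.cannula_resistance, pp.cannula_inertance
    tau_act = pp.actuator_tau
    w_min, w_max = pp.min_speed, pp.max_speed
    act_alpha = 1.0 - math.exp(-dt / tau_act)

    y = [float(v) for v in state.as_vector()]
    phase = float(state.phase)
    shifted = float(state.shifted_volume)
    e_lv = state.lv_ees_eff if state.lv_ees_eff else params.lv_ees
    e_rv = state.rv_ees_eff if state.rv_ees_eff else params.rv_ees
    omega = getattr(controller, "initial_speed", 2100.0)

    cur = params
    t_trans = schedule.transition_time if schedule is not None else None
    if schedule is not None:
        post_params = schedule.stepped_params(params)
        shift_vol = schedule.shift_volume
        shift_dur = schedule.shift_duration
        shift_rate = shift_vol / shift_dur if shift_vol else 0.0
        t_shift_end = (t_trans + shift_dur) if shift_vol else t_trans
    else:
        shift_rate = 0.0
        t_shift_end = -1.0

    def bind(p: CVSParameters):
        return (
            p.c_la, p.c_ra, p.c_sa, p.c_sv, p.c_pa, p.c_pv,
            p.la_v0, p.ra_v0, p.sa_v0, p.sv_v0, p.pa_v0, p.pv_v0,
            p.r_mv, p.r_av, p.r_tv, p.r_pv, p.r_sv_ra, p.r_pv_la,
            p.svr, p.pvr, p.lv_v0, p.lv_edp_c, p.lv_edp_s,
            p.rv_v0, p.rv_edp_a, p.rv_edp_b,
            p.heart_rate, p.systolic_fraction,
            p.lv_collapse_floor, p.lv_collapse_width, p.lv_collapse_res,
        )

    (c_la, c_ra, c_sa, c_sv, c_pa, c_pv,
     la_v0, ra_v0, sa_v0, sv_v0, pa_v0, pv_v0,
     r_mv, r_av, r_tv, r_pvv, r_ret, r_pret,
     svr, pvr, lv_v0, lv_a, lv_b, rv_v0, rv_a, rv_b,
     hr, sysfrac, vfloor, vwidth, rcol) = bind(cur)
    period = 60.0 / hr
    t_sys = sysfrac * period
    pi = math.pi
    exp = math.exp
    log1p = math.log1p
    sin = math.sin
    switched = schedule is None

    def deriv(v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv, v_res,
              q_lpm, ph, q_shift, w):
        # activation
        if ph >= period:
            ph -= period
        if ph < t_sys:
            s = sin(pi * ph / t_sys)
            act = s * s
        else:
            act = 0.0
        one_m = 1.0 - act
        p_la = (v_la - la_v0) / c_la
        p_ra = (v_ra - ra_v0) / c_ra
        p_sa = (v_sa - sa_v0) / c_sa
        p_sv = (v_sv - sv_v0) / c_sv
        p_pa = (v_pa - pa_v0) / c_pa
        p_pv = (v_pv - pv_v0) / c_pv
        arg = (v_lv - lv_v0) / lv_b
        if arg > -0.9:
            p_ed_lv = lv_a * log1p(arg)
        else:
            p_ed_lv = lv_a * (-2.302585092994046 + (arg + 0.9) * 10.0)
        p_lv = act * e_lv * (v_lv - lv_v0) + one_m * p_ed_lv
        p_rv = (act * e_rv * (v_rv - rv_v0)
                + one_m * rv_a * (1.0 - exp(-rv_b * (v_rv - rv_v0))))
        dp = p_la - p_lv
        q_mv = dp / r_mv if dp > 0.0 else 0.0
        dp = p_lv - p_sa
        q_av = dp / r_av if dp > 0.0 else 0.0
        dp = p_ra - p_rv
        q_tv = dp / r_tv if dp > 0.0 else 0.0
        dp = p_rv - p_pa
        q_puv = dp / r_pvv if dp > 0.0 else 0.0
        q_sys = (p_sa - p_sv) / svr
        q_ret = (p_sv - p_ra) / r_ret
        q_pulm = (p_pa - p_pv) / pvr
        q_pret = (p_pv - p_la) / r_pret
        q_p = q_lpm * (1000.0 / 60.0)
        # pump momentum balance (flow in L/min)
        head = (a0 * w * w + a1 * w * q_lpm
                + a2 * q_lpm * abs(q_lpm))
        if v_lv < vfloor + 8.0 * vwidth:
            r_eff = r_can + rcol / (1.0 + exp((v_lv - vfloor) / vwidth))
        else:
            r_eff = r_can
        dq = (head - (p_sa - p_lv) - r_eff * q_lpm) / l_can
        return (
            q_pret - q_mv,
            q_mv - q_av - q_p,
            q_av + q_p - q_sys,
            q_sys - q_ret + q_shift,
            q_ret - q_tv,
            q_tv - q_puv,
            q_puv - q_pulm,
            q_pulm - q_pret,
            -q_shift,
            dq,
            p_la, p_lv, p_sa, p_ra, p_rv, p_pa,
            q_sys, q_pulm,
        )

    (v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv, v_res, q_lpm) = y
    half = 0.5 * dt
    sixth = dt / 6.0
    prev_p_lv = None
    prev_p_rv = None

    starling = (params.lv_starling_gain, params.lv_starling_ref,
                params.lv_starling_min, params.lv_starling_max,
                params.rv_starling_gain, params.rv_starling_ref,
                params.rv_starling_min, params.rv_starling_max)

    for i in range(n_steps):
        t = i * dt
        # --- scenario schedule -------------------------------------------
        q_shift = 0.0
        if schedule is not None:
            if not switched and t >= t_trans:
                cur = post_params
                (c_la, c_ra, c_sa, c_sv, c_pa, c_pv,
                 la_v0, ra_v0, sa_v0, sv_v0, pa_v0, pv_v0,
                 r_mv, r_av, r_tv, r_pvv, r_ret, r_pret,
                 svr, pvr, lv_v0, lv_a, lv_b, rv_v0, rv_a, rv_b,
                 hr, sysfrac, vfloor, vwidth, rcol) = bind(cur)
                period = 60.0 / hr
                t_sys = sysfrac * period
                switched = True
            if shift_rate and t_trans <= t < t_shift_end:
                q_shift = shift_rate

        # --- beat clock ---------------------------------------------------
        if phase >= period:
            phase -= period
            beat_onsets.append(t)
            if prev_p_lv is not None:
                (g_lv, ref_lv, lv_lo, lv_hi,
                 g_rv, ref_rv, rv_lo, rv_hi) = starling
                f = 1.0 + g_lv * (prev_p_lv - ref_lv)
                f = lv_lo if f < lv_lo else (lv_hi if f > lv_hi else f)
                e_lv = cur.lv_ees * f
                f = 1.0 + g_rv * (prev_p_rv - ref_rv)
                f = rv_lo if f < rv_lo else (rv_hi if f > rv_hi else f)
                e_rv = cur.rv_ees * f

        # --- RK4 ----------------------------------------------------------
        d1 = deriv(v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv, v_res,
                   q_lpm, phase, q_shift, omega)
        d2 = deriv(v_la + half * d1[0], v_lv + half * d1[1],
                   v_sa + half * d1[2], v_sv + half * d1[3],
                   v_ra + half * d1[4], v_rv + half * d1[5],
                   v_pa + half * d1[6], v_pv + half * d1[7],
                   v_res + half * d1[8], q_lpm + half * d1[9],
                   phase + half, q_shift, omega)
        d3 = deriv(v_la + half * d2[0], v_lv + half * d2[1],
                   v_sa + half * d2[2], v_sv + half * d2[3],
                   v_ra + half * d2[4], v_rv + half * d2[5],
                   v_pa + half * d2[6], v_pv + half * d2[7],
                   v_res + half * d2[8], q_lpm + half * d2[9],
                   phase + half, q_shift, omega)
        d4 = deriv(v_la + dt * d3[0], v_lv + dt * d3[1],
                   v_sa + dt * d3[2], v_sv + dt * d3[3],
                   v_ra + dt * d3[4], v_rv + dt * d3[5],
                   v_pa + dt * d3[6], v_pv + dt * d3[7],
                   v_res + dt * d3[8], q_lpm + dt * d3[9],
                   phase + dt, q_shift, omega)
        v_la += sixth * (d1[0] + 2.0 * (d2[0] + d3[0]) + d4[0])
        v_lv += sixth * (d1[1] + 2.0 * (d2[1] + d3[1]) + d4[1])
        v_sa += sixth * (d1[2] + 2.0 * (d2[2] + d3[2]) + d4[2])
        v_sv += sixth * (d1[3] + 2.0 * (d2[3] + d3[3]) + d4[3])
        v_ra += sixth * (d1[4] + 2.0 * (d2[4] + d3[4]) + d4[4])
        v_rv += sixth * (d1[5] + 2.0 * (d2[5] + d3[5]) + d4[5])
        v_pa += sixth * (d1[6] + 2.0 * (d2[6] + d3[6]) + d4[6])
        v_pv += sixth * (d1[7] + 2.0 * (d2[7] + d3[7]) + d4[7])
        v_res += sixth * (d1[8] + 2.0 * (d2[8] + d3[8]) + d4[8])
        q_lpm += sixth * (d1[9] + 2.0 * (d2[9] + d3[9]) + d4[9])
        shifted += q_shift * dt
        phase += dt

        # record using stage-1 pressures (value at the start of the step)
        p_la_s, p_lv_s, p_sa_s, p_ra_s, p_rv_s, p_pa_s = d1[10:16]
        q_sys_s, q_pulm_s = d1[16], d1[17]
        prev_p_lv = p_lv_s
        prev_p_rv = p_rv_s

        # --- controller + actuator ---------------------------------------
        new_beat = beat_onsets and beat_onsets[-1] == t
        cmd = controller.step(t, p_lv_s, q_lpm, omega, bool(new_beat))
        if cmd < w_min:
            cmd = w_min
        elif cmd > w_max:
            cmd = w_max
        omega += act_alpha * (cmd - omega)

        out["p_la"][i] = p_la_s
        out["p_lv"][i] = p_lv_s
        out["p_sa"][i] = p_sa_s
        out["p_ra"][i] = p_ra_s
        out["p_rv"][i] = p_rv_s
        out["p_pa"][i] = p_pa_s
        out["q_sys"][i] = q_sys_s / MLPS_PER_LPM
        out["q_pulm"][i] = q_pulm_s / MLPS_PER_LPM
        out["q_pump"][i] = q_lpm
        out["speed_rpm"][i] = omega
        out["v_lv"][i] = v_lv
        for name in internal_names:
            out[name][i] = controller.internal_value(name)

        if not (math.isfinite(v_lv) and math.isfinite(q_lpm)
                and math.isfinite(v_sv)):
            raise FloatingPointError(
                f"simulation became non-finite at t={t:.4f} s "
                f"(v_lv={v_lv}, q_pump={q_lpm})")

    # write back final state
    for name, val in zip(_STATE_FIELDS,
                         (v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv,
                          v_res, q_lpm)):
        setattr(state, name, val)
    state.phase = phase
    state.shifted_volume = shifted
    state.lv_ees_eff = e_lv
    state.rv_ees_eff = e_rv

    return HemodynamicTrace(
        dt=dt,
        channels=out,
        beat_onsets=np.asarray(beat_onsets),
        meta={
            "duration": duration,
            "controller": type(controller).__name__,
            "scenario": schedule.name if schedule is not None else None,
            "collapse_floor": params.lv_collapse_floor,
        },
    )
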