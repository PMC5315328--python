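"""Rotary blood pump surrogate.

A centrifugal LVAD is modelled by a static pressure-flow-speed
characteristic plus cannula dynamics:

    H(omega, Q) = a0*omega^2 + a1*omega*Q + a2*Q^2          [mmHg]
    L * dQ/dt   = H - (P_ao - P_lv) - R * Q                  [momentum]

with Q in L/min and omega in rpm.  The speed actuator is a first-order
lag toward the commanded mean speed, hard-limited below at the minimum
operational speed of 1800 rpm while a controller is engaged.

The characteristic coefficients are not published for the device on the
bench; the defaults are fitted so the tuned loop reproduces the printed
operating points (2100 rpm <-> ~5.2 L/min at baseline, with the observed
1793-2295 rpm speed range spanning roughly 2-7 L/min across scenarios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PumpParameters", "PumpState", "pump_head",
           "pump_flow_derivative", "speed_actuator"]


@dataclass
class PumpParameters:
    """Pump characteristic, cannula and actuator parameters."""

    a0: float = 2.66e-5      # mmHg/rpm^2 (shutoff head coefficient)
    a1: float = 0.0          # mmHg.min/(rpm.L)
    a2: float = -1.05        # mmHg.min^2/L^2 (head droop with flow)
    cannula_resistance: float = 1.2    # mmHg/(L/min)
    cannula_inertance: float = 0.35    # mmHg.s/(L/min)
    actuator_tau: float = 0.2          # s
    min_speed: float = 1800.0          # rpm
    max_speed: float = 3000.0          # rpm

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.a2 > 0:
            raise ValueError("a2 must be <= 0 (head falls with flow)")
        if not self.min_speed < self.max_speed:
            raise ValueError("min_speed must be below max_speed")
        if self.cannula_inertance <= 0 or self.actuator_tau <= 0:
            raise ValueError("inertance and actuator tau must be positive")


@dataclass
class PumpState:
    """Pump rotational speed (rpm) and flow (L/min)."""

    speed: float
    flow: float = 0.0


def pump_head(flow: float, speed: float, params: PumpParameters) -> float:
    """Differential pressure (mmHg) generated at ``speed`` rpm, ``flow`` L/min.

    a0*w^2 + a1*w*Q + a2*Q*|Q|: the flow-droop term is odd in Q so that
    transient reverse flow (regurgitation at low speed) sees the mirrored
    characteristic instead of a spurious head gain.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return (params.a0 * speed * speed + params.a1 * speed * flow
            + params.a2 * flow * abs(flow))


def pump_flow_derivative(state: PumpState, p_lv: float, p_ao: float,
                         params: PumpParameters,
                         extra_inlet_resistance: float = 0.0) -> float:
    """dQ/dt (L/min per s) from the cannula momentum balance.

    ``extra_inlet_resistance`` is the collapse guard the plant raises when
    the ventricle approaches its residual volume.  Flow may transiently go
    negative (regurgitation at low speed).
    """
    if not (math.isfinite(p_lv) and math.isfinite(p_ao)):
        raise FloatingPointError("non-finite pressures")
    head = pump_head(state.flow, state.speed, params)
    resistance = params.cannula_resistance + extra_inlet_resistance
    return (head - (p_ao - p_lv) - resistance * state.flow) / params.cannula_inertance


def speed_actuator(commanded: float, current: float, dt: float,
                   params: PumpParameters, engaged: bool = True) -> float:
    """First-order approach of the pump speed toward the clamped command."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cmd = min(max(commanded, params.min_speed if engaged else 0.0),
              params.max_speed)
    alpha = 1.0 - math.exp(-dt / params.actuator_tau)
    new = current + alpha * (cmd - current)
    if engaged and new < params.min_speed:
        new = params.min_speed
    return new
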