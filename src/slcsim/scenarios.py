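"""Experimental protocol: baseline heart failure and the three transitions.

Every run starts with 120 s of the baseline left-ventricular-failure
condition at rest, then steps the loop parameters instantaneously to one
of three patient states and continues for another 120 s:

* ``exercise``    — HR 60->90 bpm, SVR 1300->600, PVR 110->40
  dyne.s.cm^-5, contractility index 1040->1880 mmHg/s, and 700 mL of
  fluid shifted from the venous reservoir into the circulation (the
  muscle pump raising venous return);
* ``blood_loss``  — HR 60->65 bpm, SVR 1300->1635, PVR 110->210
  (vasoconstriction), 300 mL shifted out of the circulation;
* ``lvc_reduction`` — contractility index 1040->25 mmHg/s (left
  ventricular contractility eliminated), everything else unchanged.

Parameter steps are instantaneous; fluid shifts ramp linearly over at
most 20 s.  The schedules ship as a data file mirroring the bench's
parameter table and may be overridden from a user config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import yaml

from .plant import CVSParameters, fluid_shift_flow

__all__ = ["ScenarioSchedule", "SCENARIO_NAMES", "build_scenario",
           "apply_schedule", "load_scenario_table"]

SCENARIO_NAMES = ("baseline", "exercise", "blood_loss", "lvc_reduction")


def load_scenario_table(path: Optional[str] = None) -> dict:
    """Load the scenario parameter table (shipped YAML by default)."""
    if path is None:
        text = (resources.files("slcsim.data") / "scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass
class ScenarioSchedule:
    """One experiment: pre/post durations, parameter steps, fluid shift."""

    name: str
    pre_duration: float = 120.0       # s at baseline before the step
    post_duration: float = 120.0      # s after the step
    steps: dict = field(default_factory=dict)   # CVSParameters field -> value
    shift_volume: float = 0.0         # mL into the circulation (+) / out (-)
    shift_duration: float = 20.0      # s

    def __post_init__(self) -> None:
        if self.pre_duration <= 0 or self.post_duration <= 0:
            raise ValueError("durations must be positive")
        if self.shift_duration <= 0 or self.shift_duration > 20.0:
            raise ValueError("shift duration must lie in (0, 20] s")

    @property
    def transition_time(self) -> float:
        return self.pre_duration

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.post_duration

    def stepped_params(self, base: CVSParameters) -> CVSParameters:
        """Parameters after the instantaneous transition step."""
        return replace(base, **self.steps) if self.steps else base

    def shift_flow(self, t: float) -> float:
        """Scripted reservoir->circulation flow (mL/s) at time ``t``."""
        if self.shift_volume == 0.0:
            return 0.0
        return fluid_shift_flow(self.shift_volume, self.shift_duration,
                                self.transition_time, t)


def build_scenario(name: str, pre_duration: float = 120.0,
                   post_duration: float = 120.0,
                   table: Optional[dict] = None) -> ScenarioSchedule:
    """Construct the schedule for a named scenario.

    ``table`` overrides the shipped parameter table (same YAML layout).
    """
    tab = table if table is not None else load_scenario_table()
    if name not in tab:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(tab)}")
    row = tab[name]
    steps: dict = {}
    if name != "baseline":
        steps = {
            "heart_rate": float(row["heart_rate_bpm"]),
            "svr_dyne": float(row["svr_dyne_s_cm5"]),
            "pvr_dyne": float(row["pvr_dyne_s_cm5"]),
            "c_lv": float(row["c_lv_mmhg_s"]),
        }
    return ScenarioSchedule(
        name=name,
        pre_duration=pre_duration,
        post_duration=post_duration,
        steps=steps,
        shift_volume=float(row.get("fluid_shift_ml", 0.0)),
        shift_duration=float(row.get("fluid_shift_duration_s", 20.0)),
    )


def apply_schedule(schedule: ScenarioSchedule, t: float,
                   base: CVSParameters) -> tuple[CVSParameters, float]:
    """Parameters in force at time ``t`` plus the active shift flow (mL/s).

    Idempotent: re-applying after the transition changes nothing further.
    """
    if t >= schedule.transition_time:
        return schedule.stepped_params(base), schedule.shift_flow(t)
    return base, 0.0
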