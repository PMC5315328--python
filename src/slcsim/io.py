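"""Trace/summary serialization and run configuration.

Traces are written as plain CSV with a header row (``time_s`` first,
then the standard channels); beat onsets and metadata go to a JSON
sidecar next to the CSV.  Run configuration is YAML with dotted-free
nested sections for plant/pump overrides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .plant import EXTRA_CHANNELS, TRACE_CHANNELS, CVSParameters, \
    HemodynamicTrace
from .pump import PumpParameters

__all__ = ["RunConfig", "load_config", "write_trace_csv", "read_trace_csv",
           "write_json", "read_json"]


@dataclass
class RunConfig:
    """Configuration of one scenario run."""

    scenario: str = "baseline"
    controller: str = "csc"            # 'slc' | 'csc'
    k: float = 1.0
    csc_speed: float = 2100.0
    dt: float = 5e-4
    pre_duration: float = 120.0
    post_duration: float = 120.0
    summary_window: float = 30.0
    seed: int = 0
    plant: dict = field(default_factory=dict)   # CVSParameters overrides
    pump: dict = field(default_factory=dict)    # PumpParameters overrides
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        from .scenarios import SCENARIO_NAMES
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.controller not in ("slc", "csc"):
            raise ValueError(f"unknown controller {self.controller!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pre_duration <= 0 or self.post_duration <= 0:
            raise ValueError("durations must be positive")
        valid_plant = {f.name for f in dc_fields(CVSParameters)}
        valid_pump = {f.name for f in dc_fields(PumpParameters)}
        for key in self.plant:
            if key not in valid_plant:
                raise ValueError(f"unknown plant parameter {key!r}")
        for key in self.pump:
            if key not in valid_pump:
                raise ValueError(f"unknown pump parameter {key!r}")

    def plant_params(self) -> CVSParameters:
        return CVSParameters(**self.plant)

    def pump_params(self) -> PumpParameters:
        return PumpParameters(**self.pump)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides win over the file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def write_trace_csv(trace: HemodynamicTrace, path: str | Path,
                    sidecar: bool = True) -> None:
    """Write a trace as CSV (+ JSON sidecar with beat onsets/metadata)."""
    path = Path(path)
    df = trace.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")
    if sidecar:
        meta = {"dt": trace.dt,
                "beat_onsets": [float(t) for t in trace.beat_onsets],
                "meta": _jsonable(trace.meta)}
        path.with_suffix(".beats.json").write_text(json.dumps(meta))


def read_trace_csv(path: str | Path) -> HemodynamicTrace:
    """Read a trace CSV written by :func:`write_trace_csv`.

    The JSON sidecar restores beat onsets; without it, onsets are left
    empty and the sample period is inferred from the time column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"trace CSV {path} lacks a time_s column")
    if len(df) < 2:
        raise ValueError(f"trace CSV {path} holds fewer than 2 samples")
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    channels = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "time_s"}
    missing = [c for c in TRACE_CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"trace CSV {path} lacks channels: {missing}")
    onsets = np.empty(0)
    meta: dict = {}
    side = path.with_suffix(".beats.json")
    if side.exists():
        data = json.loads(side.read_text())
        onsets = np.asarray(data.get("beat_onsets", []), dtype=float)
        meta = data.get("meta", {})
        dt = float(data.get("dt", dt))
    return HemodynamicTrace(dt=dt, channels=channels, beat_onsets=onsets,
                            meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2,
                                     sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
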