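"""Shared fixtures: cached full-protocol runs and the PID step experiment.

Full 240 s scenario runs are the expensive objects here (a few seconds
each); they are computed once per session and shared by every test that
inspects them.
"""

import pytest

from slcsim.experiment import run_scenario, run_step_experiment


@pytest.fixture(scope="session")
def scenario_run():
    """Factory returning the (cached) full protocol run for a
    (scenario, controller) pair with the shipped default configuration."""
    cache = {}

    def get(scenario: str, controller: str):
        key = (scenario, controller)
        if key not in cache:
            cache[key] = run_scenario(scenario, controller)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def step_trace():
    """The 1.80 -> 5.2 L/min reference-step tuning experiment."""
    return run_step_experiment()
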