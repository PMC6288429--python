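"""Shared fixtures.

Heavy simulations (steady-state pacing, clamp protocols) are computed once
per session and shared across tests; problem sizes are documented in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest

from hfmicro import core, model
from hfmicro.microdomain import case_definition
from hfmicro.phospho import PhosphoConfig
from hfmicro.protocols import run_case_experiment, run_voltage_clamp


@pytest.fixture(scope="session")
def case_pacing():
    """Lazy cache of case pacing experiments keyed by (case_id, stimulated,
    recorded_beats)."""
    cache = {}

    def get(case_id: int, stimulated: bool, recorded_beats: int = 3,
            conditioning_beats: int = 1000):
        key = (case_id, stimulated, recorded_beats, conditioning_beats)
        if key not in cache:
            cache[key] = run_case_experiment(
                case_id, stimulated, recorded_beats=recorded_beats,
                conditioning_beats=conditioning_beats, record=("v",))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def case_clamp():
    """Lazy cache of voltage-clamp runs keyed by (case_id, stimulated)."""
    cache = {}

    def get(case_id: int, stimulated: bool):
        key = (case_id, stimulated)
        if key not in cache:
            case = case_definition(case_id, stimulated=stimulated)
            cache[key] = run_voltage_clamp(
                case.params, PhosphoConfig(stimulated=stimulated),
                fractions=case.fractions)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rest_state():
    """Well-relaxed unstimulated resting state of the baseline reduction."""
    p = core.baseline_params()
    y = core.initial_state()
    _, states = model.run_free(y, p, 20000.0)
    return states[-1]
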