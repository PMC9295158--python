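"""Shared fixtures.

The heavy artifacts (reference diagram, closed-loop runs, identified model)
are session-scoped so the acceptance-style tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from cbcswitch import ToggleParams, continue_equilibria

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from cbcswitch.cbc import CBCConfig, OdeTogglePlant, run_cbc
from cbcswitch.controllers import (
    MPCConfig,
    MPCController,
    PController,
    PControllerConfig,
    PulseSpec,
    generate_id_data,
    identify_lti,
)

#: identification / experiment protocol seed used throughout
PROTOCOL_SEED = 1


@pytest.fixture(scope="session")
def params() -> ToggleParams:
    return ToggleParams()


@pytest.fixture(scope="session")
def diagram(params):
    """Reference bifurcation diagram at aTc = 25 (the dashed curve)."""
    return continue_equilibria(params, 25.0)


@pytest.fixture(scope="session")
def p_cbc_result(params):
    """Long-form deterministic CBC run with the proportional controller:
    30 references from 1800 to 0, fixed 9 h 55 min dwell."""
    plant = OdeTogglePlant(params)
    ctrl = PController(PControllerConfig(Kp=0.0016))
    return run_cbc(plant, ctrl, CBCConfig())


@pytest.fixture(scope="session")
def id_datasets(params):
    """Training and held-out pulse-response records (seeded)."""
    spec = PulseSpec()
    train = generate_id_data(params, spec, seed=PROTOCOL_SEED)
    held_out = generate_id_data(params, spec, seed=PROTOCOL_SEED + 1)
    return train, held_out


@pytest.fixture(scope="session")
def lti_model(id_datasets):
    train, _ = id_datasets
    return identify_lti(train, order=2)


@pytest.fixture(scope="session")
def mpc_cbc_result(params, lti_model):
    """Deterministic CBC run with the MPC stack (gamma = 0.3)."""
    plant = OdeTogglePlant(params)
    ctrl = MPCController(lti_model, MPCConfig(gamma=0.3))
    return run_cbc(plant, ctrl, CBCConfig(start=1200.0, end=0.0, n_points=30))
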