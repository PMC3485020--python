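import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import limbloads as ll
from limbloads.io import RunConfig
from limbloads.sensitivity import _prepare_kinematics


@pytest.fixture(scope="session")
def jump_trial():
    """The default synthetic counter-movement jump (noise-free, seed 0)."""
    return ll.generate_jump(ll.JumpParams())


@pytest.fixture(scope="session")
def model(jump_trial):
    return jump_trial.model


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def jump_kin(jump_trial, model, config):
    """Filtered, reconstructed, differentiated segment kinematics."""
    return _prepare_kinematics(jump_trial.markers, model, config)


@pytest.fixture(scope="session")
def jump_wrenches(jump_kin, jump_trial, model):
    return ll.solve_chain(jump_kin, jump_trial.ground_reaction,
                          model.inertias, model.joint_centres)


@pytest.fixture(scope="session")
def battery_results(jump_trial, config, model):
    """Full six-condition battery on the default trial (shared, ~20 s)."""
    return ll.run_battery(jump_trial.markers, jump_trial.ground_reaction,
                          jump_trial.params.subject, config, model=model)


@pytest.fixture(scope="session")
def reference_anthro():
    return ll.SubjectAnthro(mass=83.5, height=1.79)
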