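import numpy as np
import pytest

from reachdecomp.pipeline import decompose_cohort
from reachdecomp.preprocess import preprocess_recording
from reachdecomp.segment import decompose_velocity
from reachdecomp.simulate import SimParams, simulate_participant


@pytest.fixture(scope="session")
def short_params():
    """A 10-s task keeps unit tests fast; kinematics are unchanged."""
    return SimParams(task_duration_s=10.0, seed=11)


@pytest.fixture(scope="session")
def healthy_recording(short_params):
    return simulate_participant(short_params).recordings["right"]


@pytest.fixture(scope="session")
def healthy_velocity(healthy_recording):
    return preprocess_recording(healthy_recording)


@pytest.fixture(scope="session")
def healthy_elements(healthy_velocity):
    kept, _ = decompose_velocity(healthy_velocity)
    return kept


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
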