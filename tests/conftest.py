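import numpy as np
import pytest

from mam.network import ModelConfig, MAMModel
from mam.skeleton_io import N_DIMS, N_JOINTS, PoseSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """A short random but valid pose sequence at 25 fps."""
    coords = rng.normal(size=(40, N_JOINTS, N_DIMS))
    return PoseSequence(subject_id="fixture", fps=25.0, coords=coords)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained model (short instances) shared across tests."""
    return MAMModel(ModelConfig(T=12, step=8, seed=7))


@pytest.fixture(scope="session")
def tiny_instances():
    rng = np.random.default_rng(99)
    return rng.normal(size=(3, 12, N_DIMS, N_JOINTS, N_JOINTS)).astype(np.float32)
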