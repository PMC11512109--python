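import numpy as np
import pytest

from rootangle.config import RunConfig
from rootangle.scenes import SceneTruth, generate_scene


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def clean_scene():
    """One plant, 90-degree spread, no noise or occlusion."""
    root, seed, truth = generate_scene(SceneTruth(true_angle=90.0))
    return root, seed, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
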