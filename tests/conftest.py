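import numpy as np
import pytest

from fogpose.simulate import SimConfig, generate_template_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def template_dataset():
    """Small labeled height-template set (2 bodies, 1 noise repetition)
    shared by classifier tests."""
    templates, labels = generate_template_dataset(
        n_bodies=2, n_noise_reps=1, config=SimConfig(), seed=3
    )
    return templates, labels
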