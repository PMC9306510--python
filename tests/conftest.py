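import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from psckit.detect import build_template
from psckit.simulate import SimulationConfig

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

FS = 10_000.0


@pytest.fixture(scope="session")
def ipsc_template():
    return build_template(3.0, 12.0, FS)


@pytest.fixture
def quiet_config():
    """Short noise-free recording configuration."""
    return SimulationConfig(duration=5.0, noise_sd=0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)

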