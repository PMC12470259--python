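import numpy as np
import pytest

from hippseg.model import ModelConfig
from hippseg.phantom import fixture_volumes


@pytest.fixture(scope="session")
def bench_volumes():
    """The standard phantom benchmark: 20 subjects x 12 slices at 64 x 64."""
    return fixture_volumes()


@pytest.fixture(scope="session")
def small_config():
    """A 64 x 64 narrow model — the configuration used for desk-scale runs."""
    return ModelConfig(input_height=64, input_width=64, base_channels=8, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
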