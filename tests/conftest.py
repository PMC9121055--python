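import numpy as np
import pytest

from linacvsm import model as model_mod
from linacvsm import synthetic


@pytest.fixture(scope="session")
def beam_config():
    """Default 6 MV-class synthetic beam configuration."""
    return synthetic.SourceTruthConfig(seed=12345)


@pytest.fixture(scope="session")
def beam_array(beam_config):
    """One million particles of the default synthetic beam."""
    return synthetic.generate_synthetic_phsp(beam_config, 1_000_000)


@pytest.fixture(scope="session")
def beam_model(beam_array):
    """Virtual source model built from the shared synthetic beam."""
    return model_mod.build_model(beam_array)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
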