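import numpy as np
import pytest

from hbpnet import NetConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest architecture that exercises every stage (fast to run)."""
    return NetConfig(stage_widths=(2, 3, 4, 5), head_widths=(2, 3, 4, 3, 1),
                     input_dims=(8, 16, 16))


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=11)
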