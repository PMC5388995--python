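import numpy as np
import pytest

from artcea import build_pair, default_config
from artcea.pipeline import build_retention_curves


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def pair(config):
    return build_pair(config)


@pytest.fixture(scope="session")
def curves(config):
    return build_retention_curves(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_110_412)
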