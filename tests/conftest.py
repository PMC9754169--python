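import numpy as np
import pytest

from ctdense import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A 9 x 24 x 24 phantom: big enough for organs, fast for unit tests."""
    return PhantomConfig(shape=(9, 24, 24), seed=7)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_cfg):
    return generate_phantom(tiny_cfg)
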