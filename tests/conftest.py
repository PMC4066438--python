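import numpy as np
import pytest

from sporedrive import build_default_genome


@pytest.fixture(scope="session")
def genome():
    return build_default_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140624)
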