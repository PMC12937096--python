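import numpy as np
import pytest

from jmdpd import load_forcefield


@pytest.fixture(scope="session")
def ff():
    """The shipped default force field."""
    return load_forcefield("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
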