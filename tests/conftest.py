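import numpy as np
import pytest
from hypothesis import settings

from llpskit import load_fus_fixture

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fus():
    """The bundled canonical human FUS sequence (P35637, 526 residues)."""
    return load_fus_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220531)
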