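import numpy as np
import pytest

from mammofract.boxcount import default_qgrid
from mammofract.synthdata import CascadeSpec, multiplicative_cascade

REF_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def qgrid():
    return default_qgrid()


@pytest.fixture(scope="session")
def det_cascade():
    """Deterministic 256x256 multinomial cascade, the central analytic oracle."""
    return multiplicative_cascade(CascadeSpec(REF_WEIGHTS, depth=8, placement="fixed", seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
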