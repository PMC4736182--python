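import numpy as np
import pytest

from chipsyn import datasets
from chipsyn.hierplan import DivisionParams


@pytest.fixture(scope="session")
def gfp_target() -> str:
    return datasets.gfp_target()


@pytest.fixture(scope="session")
def default_division() -> DivisionParams:
    return DivisionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160202)
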