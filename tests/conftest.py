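import numpy as np
import pytest

from xbgroup.params import ModelParams
from xbgroup.solver import XGrid
from xbgroup.synth import default_params
from xbgroup.synth import random_params  # noqa: F401  (re-exported for tests)


@pytest.fixture(scope="session")
def params_q1() -> ModelParams:
    return default_params(q=1)


@pytest.fixture(scope="session")
def params_q3() -> ModelParams:
    return default_params(q=3)


@pytest.fixture(scope="session")
def grid(params_q1) -> XGrid:
    return XGrid(36, params_q1.tm.d)


@pytest.fixture(scope="session")
def fine_grid(params_q1) -> XGrid:
    return XGrid(72, params_q1.tm.d)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
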