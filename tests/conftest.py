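import numpy as np
import pytest

from bbbqsp.bbb import BBBParams, BBBState
from bbbqsp.immune import DiseaseParams
from bbbqsp.pk import PKParams
from bbbqsp.treatments import PDParams

MASTER_SEED = 20260129


@pytest.fixture(scope="session")
def bbb_params() -> BBBParams:
    return BBBParams()


@pytest.fixture(scope="session")
def pk_params() -> PKParams:
    return PKParams()


@pytest.fixture(scope="session")
def pd_params() -> PDParams:
    return PDParams()


@pytest.fixture(scope="session")
def disease_params() -> DiseaseParams:
    return DiseaseParams()


@pytest.fixture()
def healthy_state() -> BBBState:
    return BBBState()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
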