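import numpy as np
import pytest

from ohcm import default_params, synthetic_life_table
from ohcm.mortality import LifeTable


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    """Nobody dies: isolates transition and switching dynamics."""
    n = 101
    return LifeTable(age_min=0, qx_male=np.zeros(n), qx_female=np.zeros(n))
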