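import numpy as np
import pytest

from rsnconn.data_model import default_roi_set
from rsnconn.synthetic_data import SyntheticStudyConfig, simulate_study


@pytest.fixture(scope="session")
def roiset():
    return default_roi_set()


@pytest.fixture(scope="session")
def small_study():
    """A fixed small synthetic study (short series) shared across tests."""
    return simulate_study(SyntheticStudyConfig(seed=42, T=80))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
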