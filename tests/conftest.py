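import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from ciflint import fixtures as fx
from ciflint.core import UnitCell


TWOFOLD_A = np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]])


@pytest.fixture(scope="session")
def golden_dataset():
    """Consistent noisy P2_1/c structure + data (the no-alert path)."""
    return fx.make_dataset(fx.golden_spec())


@pytest.fixture(scope="session")
def noise_free_dataset():
    return fx.make_dataset(fx.golden_spec(sigma0=0.0, k_noise=0.0))


@pytest.fixture(scope="session")
def golden_model(golden_dataset):
    return golden_dataset.model


@pytest.fixture(scope="session")
def chiral_dataset():
    """Noisy P2_1 structure with resonant (S) signal, correct handedness."""
    return fx.make_dataset(fx.chiral_spec(resonant=True))


@pytest.fixture(scope="session")
def p21c_setting():
    from ciflint.symmetry import expand_hall
    return expand_hall("-P 2ybc")


@pytest.fixture
def simple_cell():
    return UnitCell(8.0, 9.0, 10.0, 90.0, 101.0, 90.0)
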