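import numpy as np
import pytest

from hdtfc import load_parameters, onset_schedule
from hdtfc.engine import LifeTable
from hdtfc.fileio import default_life_table, fit_packaged_curves


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return default_life_table()


@pytest.fixture(scope="session")
def zero_mortality_table() -> LifeTable:
    """No background death, wide age coverage, for analytic oracles."""
    ages = np.arange(0, 400)
    return LifeTable(ages, np.zeros_like(ages, dtype=float))


@pytest.fixture
def sf1_params():
    return load_parameters(population="SF1")


@pytest.fixture
def sf2_params():
    return load_parameters(population="SF2")


@pytest.fixture
def pfd_params():
    return load_parameters(population="PFD")


@pytest.fixture(scope="session")
def packaged_curves():
    return fit_packaged_curves()


@pytest.fixture
def cag40_schedule(packaged_curves):
    return onset_schedule(packaged_curves[40], 40, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)
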