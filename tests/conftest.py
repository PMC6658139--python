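import numpy as np
import pytest

from commsel import ChemState, MutationModel
from commsel.cli_io import make_fixture
from commsel.params import DEFAULT_FIXED, PREADAPTED_GROWTH


@pytest.fixture(scope="session")
def growth():
    return PREADAPTED_GROWTH


@pytest.fixture(scope="session")
def fixed():
    return DEFAULT_FIXED


@pytest.fixture(scope="session")
def no_death(fixed):
    return fixed.replace(delta_M=0.0, delta_H=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def newborn():
    """40 Helpers + 60 Manufacturers of length 1 at cost 0.13."""
    return make_fixture("monomorphic_newborn")


@pytest.fixture
def adult_7000():
    return make_fixture("adult_7000")


@pytest.fixture(scope="session")
def no_mutation():
    return MutationModel(P_mut=0.0)


@pytest.fixture(scope="session")
def fresh_chem():
    return ChemState(R=1.0, B=0.0, P=0.0)
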