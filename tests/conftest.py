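import pytest

from graftropy import LatticeConfig, generate_move_set
from graftropy.sampling import Environment
from graftropy.workflows import make_fixture

from helpers import small_anchored_env


@pytest.fixture(scope="session")
def moves():
    return generate_move_set()


@pytest.fixture(scope="session")
def small_lattice():
    """A small box so occupancy grids stay tiny in unit tests."""
    return LatticeConfig(box_edge=41)


@pytest.fixture(scope="session")
def free_env_small(small_lattice):
    return Environment(lattice=small_lattice, label="free")


@pytest.fixture(scope="session")
def flat_anchored_env():
    return small_anchored_env()


@pytest.fixture(scope="session")
def bump_anchored_env():
    return small_anchored_env(bump_center=20)


@pytest.fixture(scope="session")
def tiny_ugm_field():
    return make_fixture("tiny_ugm", size=41, seed=7, z0=0)
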