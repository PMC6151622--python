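import numpy as np
import pytest
from hypothesis import settings

from ppisect.direction import sample_unit_sphere
from ppisect.fixtures import FixtureSpec, make_fixture

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sampling_level4():
    return sample_unit_sphere(4)


@pytest.fixture(scope="session")
def sampling_level3():
    return sample_unit_sphere(3)


@pytest.fixture()
def two_atom_pair():
    return make_fixture(FixtureSpec("two_atom", gap=3.0, radius=1.0))


@pytest.fixture()
def two_unit_spheres_d2p5():
    """Coaxial unit spheres with centre distance 2.5 Å (minimum gap 0.5 Å)."""
    return make_fixture(FixtureSpec("two_atom", gap=0.5, radius=1.0))


@pytest.fixture()
def slab_pair():
    return make_fixture(FixtureSpec("slab_pair", n=5, gap=3.0, radius=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)
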