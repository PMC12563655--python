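import numpy as np
import pytest
from hypothesis import settings

from anionflux.model import FieldSpec, SimConfig, build_fcc, build_species

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def p3():
    return build_species("P3")


@pytest.fixture(scope="session")
def p2():
    return build_species("P2")


@pytest.fixture(scope="session")
def lattice():
    return build_fcc()


@pytest.fixture
def small_config(p3, lattice):
    """Short default-parameter run, used where only plumbing is exercised."""
    return SimConfig(
        species=p3,
        lattice=lattice,
        field=FieldSpec(0.0),
        seed=7,
        n_steps=600,
        save_every=20,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
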