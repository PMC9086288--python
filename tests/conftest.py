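import numpy as np
import pytest

from lvmetad import fixtures
from lvmetad.cv_geometry import VolumeSpec


@pytest.fixture(scope="session")
def double_well():
    return fixtures.double_well_potential()


@pytest.fixture(scope="session")
def symmetric_double_well():
    return fixtures.double_well_potential(asymmetry_kt=0.0)


@pytest.fixture(scope="session")
def host_guest():
    return fixtures.host_guest_model()


@pytest.fixture(scope="session")
def volume():
    return fixtures.host_guest_volume()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def generic_volume():
    """A volume with a tilted axis and off-origin apex (stress geometry)."""
    axis = np.array([2.0, 1.0, -0.5])
    return VolumeSpec(
        origin=np.array([0.5, -0.3, 1.2]),
        axis=axis / np.linalg.norm(axis),
        steepness=2.0,
        a0=0.4,
        rho_max=9.0,
        tau_max=1.2,
        wall_k=12.0,
    )
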