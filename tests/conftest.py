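import numpy as np
import pytest

from cortexdti import synthetic_data as sd


@pytest.fixture(scope="session")
def slab_phantom():
    """Slab ribbon, principal direction tilted 30 degrees, no noise."""
    spec = sd.PhantomSpec(geometry="slab", shape=(26, 26, 16),
                          theta_deg=30.0, sigma_deg=0.0, seed=11)
    return sd.make_phantom(spec)


@pytest.fixture(scope="session")
def shell_phantom():
    """Spherical-shell ribbon with exactly radial principal directions."""
    spec = sd.PhantomSpec(geometry="shell", shape=(44, 44, 44),
                          inner_radius=10.0, outer_radius=16.0,
                          theta_deg=0.0, sigma_deg=0.0, seed=7)
    return sd.make_phantom(spec)


@pytest.fixture(scope="session")
def gradient_scheme():
    return sd.make_gradient_scheme(n_directions=32, bval=2000.0, n_b0=1)


@pytest.fixture(scope="session")
def cohorts():
    """Default synthetic selection/training/test cohort tables."""
    return sd.make_cohorts(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
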