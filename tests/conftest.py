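import numpy as np
import pytest

from esohsi.hsi_io import HyperCube
from esohsi.phantom import (
    ChromophoreParams,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
)


@pytest.fixture(scope="session")
def wavelengths100():
    return np.linspace(500.0, 1000.0, 100)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom spec used across modules (24x24x100)."""
    return PhantomSpec(image_height=24, image_width=24, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six 24x24 phantom patients with the default stage water effect."""
    return generate_cohort(6, PhantomSpec(image_height=24, image_width=24), seed=11)


@pytest.fixture
def flat_cube(wavelengths100):
    """Spatially constant cube: every pixel carries the same spectrum."""
    rng = np.random.default_rng(5)
    spectrum = 0.2 + 0.6 * rng.random(100)
    data = np.broadcast_to(spectrum, (4, 4, 100)).copy()
    return HyperCube(data, wavelengths100, "flat")


@pytest.fixture
def noisefree_spec():
    return PhantomSpec(image_height=16, image_width=16,
                       pixel_jitter_sd=0.0, noise_sd=0.0, seed=1)
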