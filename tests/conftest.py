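import numpy as np
import pytest

from organspectra.hsi_core import make_wavelength_grid
from organspectra.synthetic import (
    GenerativeComponents,
    make_fingerprint_library,
    make_standardized_design,
    simulate_spectra,
)


@pytest.fixture(scope="session")
def grid():
    return make_wavelength_grid()


@pytest.fixture(scope="session")
def small_lib():
    """Five-organ fingerprint library on the camera grid."""
    return make_fingerprint_library(5, seed=0)


@pytest.fixture(scope="session")
def small_table(small_lib):
    """Raw (un-normalized) spectra: 4 pigs x 5 organs x 2 positions x 3
    angles x 3 repetitions with moderate noise on the fingerprint scale."""
    design = make_standardized_design(4, organs=small_lib.organs, n_positions=2)
    comps = GenerativeComponents(
        sigma2_pig=4e-7, sigma2_image=2e-7, sigma2_rep=1e-7, theta=(2e-4, -2e-4)
    )
    return simulate_spectra(design, small_lib, comps, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
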