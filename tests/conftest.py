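import numpy as np
import pytest

from imfp import synthetic as syn
from imfp.spectra import Spectrum, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return syn.make_library()


@pytest.fixture(scope="session")
def water(grid):
    return syn.water_reference(grid)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size simulated study shared by read-only tests."""
    return syn.simulate_cohort(syn.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Spectra generated exactly by the linear model: no water, no noise."""
    cfg = syn.CohortConfig(seed=7, spectral_noise_sd=0.0, water_scale_range=(0.0, 0.0))
    return syn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syn.CohortConfig(n_reference=12, n_case=8, seed=3)
    return syn.simulate_cohort(cfg)


def gaussian_spectrum(grid, center=1650.0, sigma=20.0, amplitude=1.0, **meta):
    values = amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, values, **meta)


@pytest.fixture
def gaussian_band(grid):
    return gaussian_spectrum(grid)
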