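import numpy as np
import pytest

from fnirscal.spectra_io import SpectraSet, default_grid
from fnirscal.synthetic_data import DietSpec, SyntheticConfig, simulate_excreta_dataset


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_excreta():
    """A 48-sample low-noise excreta dataset shared by read-only tests."""
    cfg = SyntheticConfig(n_samples=48, seed=7, noise_sd=1e-4)
    return simulate_excreta_dataset(cfg, DietSpec())


@pytest.fixture()
def random_spectra(rng, grid):
    """Smooth-ish random spectra on the default grid."""
    n, p = 12, grid.size
    base = np.cumsum(rng.normal(0, 0.01, (n, p)), axis=1) + 0.5
    return SpectraSet([f"s{i}" for i in range(n)], grid, base)
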