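import numpy as np
import pytest

from ramanpc.phantom import default_spec, generate_phantom
from ramanpc.spectra_io import SpectralScan


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scan():
    """2x2 grid, 1 repeat, 8 channels."""
    wn = np.linspace(100.0, 800.0, 8)
    intens = np.arange(32, dtype=float).reshape(4, 8) + 1.0
    return SpectralScan(wavenumbers=wn, intensities=intens,
                        grid_rows=2, grid_cols=2, repeats=1)


@pytest.fixture(scope="session")
def phantom_default():
    """Stock noisy 20x20 phantom (seeded)."""
    spec = default_spec(seed=11)
    scan, mask = generate_phantom(spec)
    return spec, scan, mask


@pytest.fixture(scope="session")
def phantom_noiseless():
    spec = default_spec(seed=11, gauss_sigma=0.0, shot_scale=0.0, salt_prob=0.0)
    scan, mask = generate_phantom(spec)
    return spec, scan, mask
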