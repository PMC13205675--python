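import numpy as np
import pytest

from ovamat.synthetic import (
    RamanPhantomSpec,
    default_raman_phantom,
    gen_raman_cube,
)


@pytest.fixture(scope="session")
def small_phantom():
    """3-component phantom small enough for per-test use (noise, no spikes)."""
    spec = default_raman_phantom(
        grid_shape=(16, 12), n_channels=401, noise_frac=0.01,
        spike_rate=0.0, seed=11,
    )
    return gen_raman_cube(spec) + (spec,)


@pytest.fixture()
def rank1_map():
    """Noiseless single-component cube: exact rank-1 construction."""
    axis = np.linspace(400, 2000, 201)
    spec = RamanPhantomSpec(
        n_components=1,
        peak_tables=[[(900, 20, 1.0), (1400, 30, 0.5)]],
        wavenumber_axis=axis,
        grid_shape=(8, 6),
        seed=2,
    )
    return gen_raman_cube(spec)


def _gaussian_sum(axis, table):
    """Independent reconstruction of a sum-of-Gaussians spectrum."""
    y = np.zeros_like(axis, dtype=float)
    for center, width, height in table:
        y += height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return y


@pytest.fixture(scope="session")
def gaussian_sum():
    return _gaussian_sum
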