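"""Shared fixtures.

The expensive fixtures (the trained desk-scale model and the fitted default
phantom) are session-scoped and built lazily, so only the tests that need
them pay for them — and they are built exactly once per session.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hypothesis_settings

from mrsfit.basis import default_basis

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from mrsfit.grid import SpectralGrid
from mrsfit.maps import fit_volume
from mrsfit.network import desk_scale_config, train
from mrsfit.synth import PhantomConfig, make_training_set, simulate_phantom

#: Matrix dimensions of the small phantom used by fast unit tests.
SMALL_DIMS = (16, 16, 8)


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid()


@pytest.fixture(scope="session")
def basis(grid):
    return default_basis(grid)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    return PhantomConfig(dims=SMALL_DIMS, seed=5)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config, grid, basis):
    return simulate_phantom(small_phantom_config, grid=grid, basis=basis)


@pytest.fixture(scope="session")
def default_phantom(grid, basis):
    """The full-geometry phantom (64 x 64 x 32) with default statistics."""
    return simulate_phantom(PhantomConfig(seed=3), grid=grid, basis=basis)


@pytest.fixture(scope="session")
def trained_model(grid, basis):
    """Desk-scale self-supervised training: 20k spectra, 20 epochs."""
    spectra, _ = make_training_set(
        20000, PhantomConfig(seed=3), rng=11, grid=grid, basis=basis
    )
    return train(spectra, desk_scale_config(seed=0), grid=grid, basis=basis)


@pytest.fixture(scope="session")
def heldout_noiseless(grid, basis):
    """Noiseless spectra with known truth, unseen during training."""
    return make_training_set(
        3000, PhantomConfig(seed=3), rng=999, grid=grid, basis=basis,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def ls_maps_default(default_phantom, basis):
    volume, _, _ = default_phantom
    return fit_volume("ls", volume, basis=basis)


@pytest.fixture(scope="session")
def nn_maps_default(default_phantom, trained_model):
    volume, _, _ = default_phantom
    return fit_volume(trained_model, volume)
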