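import numpy as np
import pytest

from phototax import (
    BiasSchedule,
    DepositionSpec,
    GridSpec,
    ModelParams,
    make_deposition,
    simulate,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(nx=32, ny=64, dx=0.25)


@pytest.fixture(scope="session")
def fingering_params() -> ModelParams:
    return ModelParams(cbar=0.5, beta=2.0)


@pytest.fixture(scope="session")
def small_fingering_run(small_grid, fingering_params):
    """A short seeded run on a small grid, shared across read-only tests."""
    C0, mask = make_deposition(small_grid, DepositionSpec(cbar=0.5, seed=7))
    return simulate(
        fingering_params, small_grid, C0, BiasSchedule(),
        t_end=12.0, dt=0.01, deposition_mask=mask, seed=7, early_stop=False,
    )


def make_blob(shape, center, sigma, amplitude=1.0):
    """Gaussian blob fixture on a grid (row, col indices)."""
    ny, nx = shape
    jj, ii = np.mgrid[0:ny, 0:nx]
    cy, cx = center
    return amplitude * np.exp(-((jj - cy) ** 2 + (ii - cx) ** 2) / (2.0 * sigma**2))
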