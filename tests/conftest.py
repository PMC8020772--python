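import numpy as np
import pytest

import serialrepro as sr


@pytest.fixture(scope="session")
def grid_1d():
    return sr.Grid((64,))


@pytest.fixture(scope="session")
def grid_2d():
    return sr.Grid((32, 32))


@pytest.fixture(scope="session")
def bimodal_prior_1d(grid_1d):
    """Two landmarks on a broad background (1D study prior)."""
    return sr.make_mixture_prior(
        [([0.3], 0.004, 1.0), ([0.7], 0.004, 1.0)], grid_1d, background=0.25
    )


@pytest.fixture(scope="session")
def trimodal_prior_2d(grid_2d):
    """Three landmarks on a broad background (2D study prior)."""
    return sr.make_mixture_prior(
        [
            ([0.3, 0.35], 0.004, 1.0),
            ([0.7, 0.4], 0.004, 1.0),
            ([0.5, 0.75], 0.004, 1.0),
        ],
        grid_2d,
        background=0.25,
    )


@pytest.fixture(scope="session")
def uniform_prior_1d(grid_1d):
    return sr.normalize(np.ones(grid_1d.n_cells), grid_1d)


def random_prior(grid, seed):
    """Strictly positive random density (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    return sr.normalize(rng.random(grid.n_cells) + 0.05, grid)
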