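import numpy as np
import pytest

from paleorange import bioclim as bc
from paleorange import niche_model as nm
from paleorange import synthetic_data as syn
from paleorange.grids import LatLonGrid


@pytest.fixture(scope="session")
def small_grid() -> LatLonGrid:
    return LatLonGrid(-15, 15, -15, 15, 1.0)


@pytest.fixture(scope="session")
def climate(small_grid) -> syn.MonthlyClimate:
    spec = syn.ScenarioSpec(
        noise_sd=0.5,
        pluvial_center_lat=8.0,
        pluvial_width=6.0,
        background_precip=5.0,
    )
    return syn.generate_climate(spec, small_grid, seed=11)


@pytest.fixture(scope="session")
def stack(climate) -> bc.BioclimStack:
    return bc.build_bioclim_stack(climate)


def log_linear_truth(stack: bc.BioclimStack, coef: np.ndarray) -> np.ndarray:
    """Known log-linear intensity over standardized bioclim variables;
    the synthetic ground truth used in recovery tests."""
    X = stack.feature_matrix()
    sd = X.std(axis=0)
    z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    eta = z @ np.asarray(coef, dtype=float)
    values = np.full(stack.grid.shape, np.nan)
    values[stack.land_mask] = np.exp(eta - eta.max())
    return values


@pytest.fixture(scope="session")
def strong_truth(stack) -> np.ndarray:
    # strong signal on the aridity index only
    return log_linear_truth(stack, [0.0, 0.0, 6.0, 0.0])


@pytest.fixture(scope="session")
def occurrences(strong_truth, small_grid) -> syn.OccurrenceSet:
    return syn.generate_occurrences(strong_truth, 500, 0.0, seed=21, grid=small_grid)


@pytest.fixture(scope="session")
def background(stack):
    return nm.sample_background(stack.land_mask, 100_000, seed=31)
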