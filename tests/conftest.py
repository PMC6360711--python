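import numpy as np
import pytest

from aslpvc.core_model import TissueFractionVolume
from aslpvc.phantom import (
    LesionSpec,
    PhantomConfig,
    build_truth_sim1,
    render_series,
    synth_fractions,
)

SMALL_GRID = (24, 28, 24)


@pytest.fixture(scope="session")
def small_fractions() -> TissueFractionVolume:
    """Small procedural anatomy used by most unit tests."""
    return synth_fractions(grid_shape=SMALL_GRID, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_fractions):
    """Small Simulation-1-style truth with two small spherical lesions."""
    lesions = [
        LesionSpec(shape="sphere", center=(8, 14, 12), size=2, cbf_value=30.0),
        LesionSpec(shape="sphere", center=(16, 14, 12), size=2, cbf_value=90.0),
    ]
    cfg = PhantomConfig(grid_shape=SMALL_GRID, lesions=lesions, n_pairs=8)
    return build_truth_sim1(small_fractions, cfg)


@pytest.fixture(scope="session")
def small_lesionfree_truth(small_fractions):
    cfg = PhantomConfig(grid_shape=SMALL_GRID, lesions=[], n_pairs=8)
    return build_truth_sim1(small_fractions, cfg)


@pytest.fixture(scope="session")
def small_series(small_truth):
    return render_series(small_truth, noise_std=5.0, n_pairs=8, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
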