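import numpy as np
import pytest

from hgflip.fes import wham2d
from hgflip.synthetic import MCParams, make_window_suite, model_surface
from hgflip.umbrella import build_window_grid

SUITE_SEED = 1


@pytest.fixture(scope="session")
def surface():
    return model_surface()


@pytest.fixture(scope="session")
def reference_grid():
    """The 13 x 24 window grid over the printed coordinate ranges."""
    return build_window_grid(13, (-100.0, 100.0), 24, (-180.0, 180.0),
                             k_cpdb=100.0, k_chi=50.0)


@pytest.fixture(scope="session")
def window_suite(surface, reference_grid):
    """312 biased ensembles of 3000 samples each (fixed seed)."""
    return make_window_suite(surface, reference_grid, MCParams(seed=SUITE_SEED),
                             master_seed=SUITE_SEED)


@pytest.fixture(scope="session")
def recovered(window_suite):
    """(FESGrid, WhamResult) reweighted from the full window suite."""
    return wham2d(window_suite)


@pytest.fixture(scope="session")
def true_grid(surface, recovered):
    fes, _ = recovered
    return surface.true_grid(fes.cpdb_edges, fes.chi_edges, fes.temperature)
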