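import numpy as np
import pandas as pd
import pytest

from nichemax.grid_io import EnvStack, GridSpec
from nichemax.pipeline import run_recovery_benchmark


@pytest.fixture(scope="session")
def recovery():
    """One full synthetic-truth recovery run shared across the suite.

    Defaults: 64×64 planar grid, 6 variables (3 informative, 1 correlated
    decoy, 2 pure noise), 500 presences, 2,000 background cells, fixed seeds.
    """
    return run_recovery_benchmark(seed=0)


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=10, n_cols=10, origin_x=0.0, origin_y=10_000.0,
                    cell_size_x=1000.0, cell_size_y=1000.0, crs_tag="synthetic-planar")


@pytest.fixture
def small_stack(small_grid):
    rng = np.random.default_rng(42)
    layers = {
        "BIO1": rng.normal(12, 4, small_grid.shape),
        "BIO16": rng.normal(400, 90, small_grid.shape),
    }
    return EnvStack(small_grid, layers, "current")


def random_psd_correlation(rng, p):
    """Random well-conditioned correlation matrix via a random factor."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
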