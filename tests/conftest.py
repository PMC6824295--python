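import numpy as np
import pandas as pd
import pytest

from scdeconv.io import ExpressionMatrix
from scdeconv.fixtures import FixtureSpec, make_ground_truth


@pytest.fixture
def small_matrix():
    """3 genes x 2 observations with easy-to-track values."""
    return ExpressionMatrix(
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        "counts",
    )


@pytest.fixture(scope="session")
def ground_truth_small():
    """Shared small synthetic dataset with known ZINB parameters."""
    spec = FixtureSpec(n_types=3, n_genes=120, n_cells_per_type=200, seed=7)
    return make_ground_truth(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
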