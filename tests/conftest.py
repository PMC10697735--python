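import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230707)


@pytest.fixture
def small_binary(rng):
    """50 x 6 binary phenotype matrix with a mix of rare and common cases."""
    probs = np.array([0.1, 0.2, 0.3, 0.1, 0.4, 0.25])
    Y = (rng.random((50, 6)) < probs).astype(np.int8)
    # ensure every phenotype has at least one case
    for j in range(6):
        if Y[:, j].sum() == 0:
            Y[j, j] = 1
    return Y


@pytest.fixture
def two_block_W():
    """Block similarity: within-block 0.9, across 0.0 (two blocks of 3)."""
    W = np.full((6, 6), 0.0)
    W[:3, :3] = 0.9
    W[3:, 3:] = 0.9
    np.fill_diagonal(W, 1.0)
    return W
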