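import sys
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glp import CountMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells with hand-checkable stats."""
    counts = np.array(
        [
            [0, 0, 0, 0],   # never detected
            [2, 1, 3, 0],   # lambda 1.5, f 0.75
            [1, 1, 1, 1],   # lambda 1, f 1
        ]
    )
    return CountMatrix(
        gene_ids=["g_zero", "g_mid", "g_one"],
        cell_ids=[f"c{i}" for i in range(4)],
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def random_matrix():
    """200 genes x 50 cells of sparse Poisson-ish counts."""
    rng = np.random.default_rng(42)
    dense = rng.poisson(np.exp(rng.uniform(np.log(0.01), np.log(5), 200))[:, None],
                        size=(200, 50))
    return CountMatrix(
        gene_ids=[f"g{i:04d}" for i in range(200)],
        cell_ids=[f"c{i:03d}" for i in range(50)],
        counts=sp.csr_matrix(dense),
    )
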