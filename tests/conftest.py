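import warnings

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from transmodal.containers import CountMatrix

warnings.filterwarnings("ignore", message=".*leiden.*")
warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")


@pytest.fixture
def rna_toy():
    counts = np.array([
        [5, 0, 3, 1, 1],
        [0, 10, 4, 2, 4],
        [20, 5, 5, 5, 5],
    ])
    return CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=["c1", "c2", "c3"],
        feature_ids=[f"g{i}" for i in range(5)],
        modality="rna",
    )


@pytest.fixture
def atac_toy():
    # the 2x3 worked TF-IDF example
    counts = np.array([[1, 0, 1], [1, 1, 0]])
    return CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=["c1", "c2"],
        feature_ids=["chr1:0-100", "chr1:200-300", "chr2:0-100"],
        modality="atac",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
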