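import numpy as np
import pytest

from episeeker import GenotypeMatrix, simulate_null


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_panel():
    """3 SNPs x 6 samples, hand-coded."""
    genotypes = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [2, 0, 0, 1, 1, 0],
            [1, 1, 1, 0, 2, 0],
        ],
        dtype=np.uint8,
    )
    status = np.array([1, 0, 1, 0, 1, 0], dtype=np.int8)
    return GenotypeMatrix(("S1", "S2", "S3"), genotypes, status)


@pytest.fixture
def null_panel():
    """Seeded 40-SNP null panel with 60 cases and 60 controls."""
    return simulate_null(40, 60, 60, rng=np.random.default_rng(7)).panel
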