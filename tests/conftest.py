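import numpy as np
import pytest
import scipy.sparse as sp

import regionvec as rv


@pytest.fixture
def tiny_matrix():
    """3 cells x 4 regions with hand-set entries."""
    regions = [
        rv.GenomicRegion("chr1", 0, 500),
        rv.GenomicRegion("chr1", 1500, 2000),
        rv.GenomicRegion("chr1", 3000, 3500),
        rv.GenomicRegion("chr2", 0, 500),
    ]
    entries = sp.csr_matrix(
        np.array(
            [
                [0, 2, 1, 0],
                [1, 1, 1, 1],
                [0, 0, 0, 0],
            ],
            dtype=float,
        )
    )
    return rv.AccessibilityMatrix(["c1", "c2", "c3"], regions, entries)


@pytest.fixture
def tiny_bundle(tiny_matrix):
    """Hand-set 2-d vectors over the 4 tiny regions."""
    words = [rv.region_to_word(r) for r in tiny_matrix.regions]
    vocabulary = {w: i for i, w in enumerate(words)}
    inp = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 4.0], [-1.0, 3.0]])
    ctx = np.zeros_like(inp)
    return rv.ModelBundle(vocabulary, inp, ctx, list(tiny_matrix.regions))


@pytest.fixture(scope="session")
def small_synth():
    """2 planted types, small enough for fast training in unit tests."""
    spec = rv.SyntheticSpec(
        n_types=2, cells_per_type=40, n_regions=200, signature_size=25,
        housekeeping_size=10, p_high=0.5, p_low=0.02, p_house=0.2, seed=123,
    )
    matrix, labels, signatures = rv.generate(spec)
    return spec, matrix, labels, signatures


@pytest.fixture(scope="session")
def small_model(small_synth):
    _, matrix, _, _ = small_synth
    corpus = rv.build_documents(matrix)
    config = rv.TrainingConfig(dimension=16, epochs=5, seed=5)
    return rv.train(corpus, config, consensus=matrix.regions)
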