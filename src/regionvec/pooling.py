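"""Cell embeddings: the unweighted mean of the input vectors of each cell's
accessible regions. Cells with no in-vocabulary regions get NaN sentinel
vectors and are excluded from clustering downstream."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import scipy.sparse as sp

from .corpus import CellDocument, region_to_word
from .io_formats import AccessibilityMatrix, ModelBundle

logger = logging.getLogger(__name__)


@dataclass
class CellEmbeddingSet:
    barcodes: List[str]
    vectors: np.ndarray  # n_cells x d; NaN rows for zero-coverage cells
    coverage: np.ndarray  # per-cell count of contributing regions

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if len(self.barcodes) != self.vectors.shape[0]:
            raise ValueError("barcode count does not match vector rows")
        if len(self.coverage) != self.vectors.shape[0]:
            raise ValueError("coverage length does not match vector rows")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.coverage > 0


def pool_pattern(
    pattern: sp.csr_matrix, input_vectors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-pool vector-table rows over a binary cells x |V| pattern.

    Shared by the direct and the overlap-projected embedding paths so that
    identical patterns produce bit-identical embeddings.
    """
    pattern = sp.csr_matrix(pattern)
    pattern.sort_indices()
    coverage = np.asarray(pattern.sum(axis=1)).ravel().astype(np.int64)
    sums = pattern @ input_vectors
    vectors = np.full(sums.shape, np.nan)
    ok = coverage > 0
    vectors[ok] = sums[ok] / coverage[ok, None]
    return vectors, coverage


def embed_cell(doc: CellDocument, bundle: ModelBundle) -> tuple[np.ndarray, int]:
    """Mean of input vectors over the document's in-vocabulary words.

    Out-of-vocabulary words are skipped (and tallied in the log); a cell
    with zero in-vocabulary words gets an all-NaN vector.
    """
    rows = []
    oov = 0
    seen = set()
    for w in doc.words:
        if w in seen:  # binary semantics: duplicates collapse
            continue
        seen.add(w)
        i = bundle.vocabulary.get(w)
        if i is None:
            oov += 1
        else:
            rows.append(i)
    if oov:
        logger.info("cell %s: %d out-of-vocabulary words skipped", doc.barcode, oov)
    if not rows:
        logger.warning("cell %s has no in-vocabulary regions", doc.barcode)
        return np.full(bundle.dimension, np.nan), 0
    rows = np.sort(np.asarray(rows, dtype=np.int64))
    acc = np.zeros(bundle.dimension)
    for r in rows:  # sequential accumulation matches the sparse matmul path
        acc += bundle.input_vectors[r]
    return acc / len(rows), len(rows)


def embed_all(matrix: AccessibilityMatrix, bundle: ModelBundle) -> CellEmbeddingSet:
    """Embed every cell of the matrix; row i is the pooled embedding of the
    regions with signal in row i. Invariant to word order."""
    col_to_vocab = np.full(matrix.n_regions, -1, dtype=np.int64)
    for j, region in enumerate(matrix.regions):
        idx = bundle.vocabulary.get(region_to_word(region))
        if idx is not None:
            col_to_vocab[j] = idx
    n_oov_cols = int((col_to_vocab < 0).sum())
    if n_oov_cols:
        logger.info(
            "%d of %d matrix regions are out of the model vocabulary",
            n_oov_cols, matrix.n_regions,
        )

    pattern = matrix.binarized().tocoo()
    keep = col_to_vocab[pattern.col] >= 0
    vocab_pattern = sp.csr_matrix(
        (
            np.ones(int(keep.sum())),
            (pattern.row[keep], col_to_vocab[pattern.col[keep]]),
        ),
        shape=(matrix.n_cells, len(bundle.vocabulary)),
    )
    # duplicate (cell, vocab) pairs cannot arise from distinct matrix columns
    # unless two columns encode the same region; collapse to binary anyway
    vocab_pattern.data[:] = 1.0
    vocab_pattern.sum_duplicates()
    vocab_pattern.data[:] = 1.0
    vectors, coverage = pool_pattern(vocab_pattern, bundle.input_vectors)
    if not coverage.any():
        logger.warning("all cells have zero in-vocabulary coverage")
    return CellEmbeddingSet(list(matrix.barcodes), vectors, coverage)
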