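"""Turn an accessibility matrix into region-word documents.

Each cell becomes a document whose words are the regions with signal
(entry > 0). Word order carries no meaning, so context for the skip-gram
trainer is simulated by shuffling each document.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .io_formats import AccessibilityMatrix, GenomicRegion, _parse_word

logger = logging.getLogger(__name__)


@dataclass
class CellDocument:
    barcode: str
    words: List[str]


@dataclass
class Corpus:
    documents: List[CellDocument]
    vocabulary_counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.documents)


def region_to_word(region: GenomicRegion) -> str:
    """Encode an interval as "chrom_start_end" with plain decimal integers."""
    return f"{region.chrom}_{region.start}_{region.end}"


def word_to_region(word: str) -> GenomicRegion:
    """Inverse of region_to_word. Chromosome names may themselves contain
    underscores; coordinates are taken from the last two fields."""
    return _parse_word(word)


def build_documents(matrix: AccessibilityMatrix) -> Corpus:
    """One document per matrix row, containing the words of columns with
    entry > 0. Empty rows yield empty documents (kept for row alignment)."""
    words = [region_to_word(r) for r in matrix.regions]
    pattern = matrix.binarized()
    documents: List[CellDocument] = []
    counts: Dict[str, int] = {}
    indptr, indices = pattern.indptr, pattern.indices
    n_empty = 0
    for i, barcode in enumerate(matrix.barcodes):
        cols = indices[indptr[i]:indptr[i + 1]]
        doc_words = [words[j] for j in cols]
        if not doc_words:
            n_empty += 1
            logger.warning("cell %s has no accessible regions", barcode)
        for w in doc_words:
            counts[w] = counts.get(w, 0) + 1
        documents.append(CellDocument(barcode, doc_words))
    if n_empty:
        logger.warning("%d of %d cells have empty documents", n_empty, len(documents))
    return Corpus(documents, counts)


def shuffle_document(doc: CellDocument, rng: np.random.Generator) -> CellDocument:
    """Uniform random permutation of the document's words; input unmodified."""
    order = rng.permutation(len(doc.words))
    return CellDocument(doc.barcode, [doc.words[i] for i in order])


def epoch_rng(seed: int, epoch: int, doc_index: int) -> np.random.Generator:
    """Deterministic per-(seed, epoch, document) generator so every epoch
    re-shuffles every document with a fresh, reproducible permutation."""
    return np.random.default_rng(np.random.SeedSequence([seed, epoch, doc_index]))


def export_corpus(corpus: Corpus, path: str) -> None:
    """One document per line, space-separated words."""
    with open(path, "w") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc.words) + "\n")
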