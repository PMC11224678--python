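"""Project unseen datasets into a pre-trained model's space.

Query regions are mapped to the model's vocabulary regions by genomic
overlap; each query cell is then re-expressed as a document of reference
words and mean-pooled (E-projection). A 2D reducer fitted on reference
cell embeddings can additionally place query cells in the reference
coordinate frame without refitting (EV-projection).
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .corpus import CellDocument, Corpus, region_to_word, word_to_region
from .io_formats import AccessibilityMatrix, GenomicRegion, ModelBundle
from .pooling import CellEmbeddingSet, pool_pattern

logger = logging.getLogger(__name__)

MIN_REDUCER_CELLS = 20


@dataclass
class OverlapMap:
    """Many-to-many links from query regions to reference region indices."""

    query_regions: List[GenomicRegion]
    links: List[List[int]]
    stats: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_query = len(self.query_regions)
        if len(self.links) != n_query:
            raise ValueError("one link list required per query region")
        mapped = [ln for ln in self.links if ln]
        self.stats = {
            "n_query": n_query,
            "n_mapped": len(mapped),
            "mean_links_per_mapped_query": (
                float(np.mean([len(ln) for ln in mapped])) if mapped else 0.0
            ),
        }


def build_overlap_map(
    query: Sequence[GenomicRegion],
    reference: Sequence[GenomicRegion],
    min_overlap_frac: float = 0.0,
    best_hit: bool = False,
) -> OverlapMap:
    """Link each query region to every reference region it overlaps.

    Overlap uses half-open coordinates: min(ends) - max(starts) >= 1 bp
    (so abutting intervals do not overlap). `min_overlap_frac` additionally
    requires overlap >= frac * query width; `best_hit` keeps only the
    largest-overlap link (ties to the lower reference index).

    Sorted sweep with a running end-maximum; O((n+m) log(n+m)) for
    non-pathological region sets.
    """
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for j, r in enumerate(reference):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, j))
    index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idxs = np.array([t[2] for t in triples], dtype=np.int64)
        index[chrom] = (starts, ends, idxs, np.maximum.accumulate(ends))

    links: List[List[int]] = []
    seen_chrom = False
    for q in query:
        entry = index.get(q.chrom)
        hits: List[Tuple[int, int]] = []  # (ref index, overlap length)
        if entry is not None:
            seen_chrom = True
            starts, ends, idxs, end_cummax = entry
            hi = int(np.searchsorted(starts, q.end, side="left"))
            min_len = max(1, int(np.ceil(min_overlap_frac * q.width)))
            j = hi - 1
            while j >= 0 and end_cummax[j] > q.start:
                overlap = min(int(ends[j]), q.end) - max(int(starts[j]), q.start)
                if overlap >= min_len:
                    hits.append((int(idxs[j]), overlap))
                j -= 1
        if best_hit and hits:
            hits = [max(hits, key=lambda h: (h[1], -h[0]))]
        links.append(sorted(h[0] for h in hits))
    if query and reference and not seen_chrom:
        logger.warning(
            "query and reference share no chromosome names; all links empty"
        )
    return OverlapMap(list(query), links)


def _links_matrix(overlap_map: OverlapMap, n_reference: int) -> sp.csr_matrix:
    rows, cols = [], []
    for qi, refs in enumerate(overlap_map.links):
        for r in refs:
            rows.append(qi)
            cols.append(r)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(overlap_map.links), n_reference),
    )


def _translate_pattern(
    query_matrix: AccessibilityMatrix, overlap_map: OverlapMap, n_reference: int
) -> sp.csr_matrix:
    """Binary cells x n_reference pattern: reference words linked from each
    cell's accessible query regions, deduplicated."""
    pattern = query_matrix.binarized() @ _links_matrix(overlap_map, n_reference)
    pattern = sp.csr_matrix(pattern)
    pattern.data[:] = 1.0
    pattern.sum_duplicates()
    pattern.data[:] = 1.0
    pattern.sort_indices()
    return pattern


def translate_documents(
    query_matrix: AccessibilityMatrix,
    overlap_map: OverlapMap,
    bundle: ModelBundle,
) -> Tuple[Corpus, np.ndarray]:
    """Re-express each query cell as a document over the reference
    vocabulary. Returns the corpus and the per-cell mapped fraction
    (mapped accessible regions / accessible regions)."""
    words = bundle.words
    pattern = _translate_pattern(query_matrix, overlap_map, len(words))
    source = query_matrix.binarized()
    has_link = np.array([1.0 if ln else 0.0 for ln in overlap_map.links])
    accessible = np.asarray(source.sum(axis=1)).ravel()
    mapped = np.asarray(source @ has_link).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mapped_fraction = np.where(accessible > 0, mapped / accessible, 0.0)

    documents: List[CellDocument] = []
    counts: Dict[str, int] = {}
    indptr, indices = pattern.indptr, pattern.indices
    for i, barcode in enumerate(query_matrix.barcodes):
        doc_words = [words[j] for j in indices[indptr[i]:indptr[i + 1]]]
        for w in doc_words:
            counts[w] = counts.get(w, 0) + 1
        documents.append(CellDocument(barcode, doc_words))
    return Corpus(documents, counts), mapped_fraction


def e_project(
    query_matrix: AccessibilityMatrix,
    bundle: ModelBundle,
    min_overlap_frac: float = 0.0,
    best_hit: bool = False,
) -> CellEmbeddingSet:
    """Embed query cells with a pre-trained model: overlap-map query regions
    to the model vocabulary, pool the reference input vectors per cell.

    When the query regions equal the reference region set exactly, the
    result is bit-identical to embedding the matrix without projection.
    """
    vocab_regions = [word_to_region(w) for w in bundle.words]
    overlap_map = build_overlap_map(
        query_matrix.regions, vocab_regions,
        min_overlap_frac=min_overlap_frac, best_hit=best_hit,
    )
    if overlap_map.stats["n_mapped"] == 0:
        raise ValueError(
            "no query region overlaps any model region; check that query and "
            "reference use the same genome assembly"
        )
    pattern = _translate_pattern(query_matrix, overlap_map, len(bundle.vocabulary))
    vectors, coverage = pool_pattern(pattern, bundle.input_vectors)
    n_empty = int((coverage == 0).sum())
    if n_empty:
        logger.warning("%d query cells mapped to no reference region", n_empty)
    return CellEmbeddingSet(list(query_matrix.barcodes), vectors, coverage)


@dataclass
class ReducerModel:
    """A 2D manifold reducer (UMAP) fitted once on reference embeddings;
    query embeddings are transformed without refitting."""

    model: object
    reference_coordinates: np.ndarray
    seed: int

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.transform(vectors), dtype=np.float64)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "ReducerModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_reducer(
    reference_embeddings: CellEmbeddingSet,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ReducerModel:
    """Fit the 2D reducer on non-NaN reference cells; deterministic under
    the seed."""
    import umap  # deferred: slow import

    valid = reference_embeddings.valid_mask
    vectors = reference_embeddings.vectors[valid]
    if vectors.shape[0] < MIN_REDUCER_CELLS:
        raise ValueError(
            f"need >= {MIN_REDUCER_CELLS} cells with coverage to fit the "
            f"reducer, got {vectors.shape[0]}"
        )
    model = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
    )
    coords = np.asarray(model.fit_transform(vectors), dtype=np.float64)
    return ReducerModel(model, coords, seed)


def ev_project(
    query_embeddings: CellEmbeddingSet, reducer: ReducerModel
) -> Tuple[np.ndarray, List[str]]:
    """Transform query cell embeddings through the reference-fitted reducer
    (never refit). NaN cells are dropped with a warning. Returns the 2D
    coordinates and the barcodes they belong to, in reference frame."""
    valid = query_embeddings.valid_mask
    dropped = [
        b for b, ok in zip(query_embeddings.barcodes, valid) if not ok
    ]
    if dropped:
        logger.warning(
            "dropping %d zero-coverage cells from EV-projection: %s",
            len(dropped), ", ".join(dropped[:20]),
        )
    coords = reducer.transform(query_embeddings.vectors[valid])
    barcodes = [b for b, ok in zip(query_embeddings.barcodes, valid) if ok]
    return coords, barcodes
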