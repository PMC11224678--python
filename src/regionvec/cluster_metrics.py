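"""Clustering of cell embeddings (K-means, hierarchical, Louvain) and
partition scoring: ARI / AMI / homogeneity against ground truth, and the
Residual Average Gini Index (RAGI) when no truth labels exist.

RAGI scores a clustering by how cluster-specific marker-gene activity is,
relative to housekeeping activity: mean Gini (over clusters) of marker
activity minus mean Gini of housekeeping activity.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import igraph as ig
from sklearn import metrics as _skm
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.neighbors import NearestNeighbors

from .io_formats import AccessibilityMatrix
from .pooling import CellEmbeddingSet

logger = logging.getLogger(__name__)

METHODS = ("kmeans", "hc", "louvain")


@dataclass
class ClusterAssignment:
    barcodes: List[str]
    labels: np.ndarray  # one integer per (non-NaN) cell, contiguous 0..K-1
    method: str = ""
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.barcodes) != len(self.labels):
            raise ValueError("one label required per barcode")
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous 0..K-1")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class SignatureSets:
    """Named marker and housekeeping region-index sets for RAGI."""

    marker_sets: Dict[str, Set[int]]
    housekeeping_sets: Dict[str, Set[int]]

    def __post_init__(self) -> None:
        shared = set(self.marker_sets) & set(self.housekeeping_sets)
        if shared:
            raise ValueError(f"marker/housekeeping names overlap: {sorted(shared)}")


def _contiguous(raw: np.ndarray) -> np.ndarray:
    _, labels = np.unique(raw, return_inverse=True)
    return labels.astype(np.int64)


def _knn_graph(vectors: np.ndarray, k_graph: int) -> ig.Graph:
    """Symmetric unit-weight kNN graph: edge if either endpoint lists the
    other among its k_graph nearest neighbours."""
    n = vectors.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_graph + 1, n)).fit(vectors)
    _, idx = nn.kneighbors(vectors)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=n, edges=sorted(edges), directed=False)


def cluster(
    embeddings: CellEmbeddingSet,
    method: str,
    seed: int = 0,
    k: Optional[int] = None,
    k_graph: int = 15,
    resolution: float = 1.0,
) -> ClusterAssignment:
    """Cluster the non-NaN cells of an embedding set.

    kmeans / hc require `k`; louvain builds a symmetric kNN graph and
    optimizes modularity. Deterministic under `seed`.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    valid = embeddings.valid_mask
    vectors = embeddings.vectors[valid]
    barcodes = [b for b, ok in zip(embeddings.barcodes, valid) if ok]
    n = vectors.shape[0]
    if n == 0:
        raise ValueError("no cells with coverage to cluster")
    params: Dict[str, object] = {"seed": seed}
    if method in ("kmeans", "hc"):
        if k is None:
            raise ValueError(f"{method} requires k")
        if k > n:
            raise ValueError(f"k={k} exceeds {n} cells")
        params["k"] = k
        if method == "kmeans":
            raw = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(vectors)
        else:
            raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(vectors)
    else:
        params.update({"k_graph": k_graph, "resolution": resolution})
        graph = _knn_graph(vectors, k_graph)
        ig.set_random_number_generator(random.Random(seed))
        communities = graph.community_multilevel(resolution=resolution)
        raw = np.asarray(communities.membership)
    return ClusterAssignment(barcodes, _contiguous(np.asarray(raw)), method, params)


def _check_pair(labels_a: Sequence, labels_b: Sequence) -> None:
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label lengths differ: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) < 2:
        raise ValueError("need at least 2 items")


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    _check_pair(labels_a, labels_b)
    return float(_skm.adjusted_rand_score(labels_a, labels_b))


def ami(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted mutual information, arithmetic-mean normalization."""
    _check_pair(labels_a, labels_b)
    return float(
        _skm.adjusted_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
    )


def homogeneity(labels_true: Sequence, labels_pred: Sequence) -> float:
    """1 - H(truth | prediction) / H(truth)."""
    _check_pair(labels_true, labels_pred)
    return float(_skm.homogeneity_score(labels_true, labels_pred))


def gini(values: Sequence[float]) -> float:
    """Normalized mean absolute difference: sum_ij |xi - xj| / (2 n sum_j xj),
    in [0, (n-1)/n]. All-zero input is defined as 0 (with a warning)."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("gini needs a 1-D vector of length >= 1")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        logger.warning("gini of all-zero vector defined as 0")
        return 0.0
    n = len(x)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * total))


def _gene_cluster_activity(
    pattern, cell_labels: np.ndarray, region_idx: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Per-cluster activity of one gene: mean over the cluster's cells of the
    mean binary accessibility of the gene's regions."""
    per_cell = np.asarray(pattern[:, region_idx].mean(axis=1)).ravel()
    return np.array(
        [per_cell[cell_labels == c].mean() for c in range(n_clusters)]
    )


def ragi(
    matrix: AccessibilityMatrix,
    assignment: ClusterAssignment,
    signatures: SignatureSets,
) -> Dict[str, object]:
    """Residual Average Gini Index of a clustering.

    Per gene, activity in a cluster is the mean (over the cluster's cells)
    of the mean binary accessibility of the gene's regions; the Gini index
    of the per-cluster activity vector measures cluster specificity.
    RAGI = mean marker Gini - mean housekeeping Gini.
    """
    if assignment.n_clusters < 2:
        raise ValueError("RAGI requires >= 2 clusters")
    if not signatures.marker_sets or not signatures.housekeeping_sets:
        raise ValueError("marker and housekeeping sets must be non-empty")
    row_of = {b: i for i, b in enumerate(matrix.barcodes)}
    rows = np.array([row_of[b] for b in assignment.barcodes])
    pattern = matrix.binarized()[rows]
    labels = assignment.labels
    k = assignment.n_clusters

    def gene_ginis(sets: Mapping[str, Set[int]]) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for name, idx_set in sets.items():
            idx = np.array(sorted(i for i in idx_set if 0 <= i < matrix.n_regions))
            if len(idx) == 0:
                logger.warning("gene %s has no regions in the matrix; excluded", name)
                continue
            if len(idx) < len(idx_set):
                logger.warning(
                    "gene %s: %d of %d regions outside the matrix",
                    name, len(idx_set) - len(idx), len(idx_set),
                )
            out[name] = gini(_gene_cluster_activity(pattern, labels, idx, k))
        return out

    marker = gene_ginis(signatures.marker_sets)
    house = gene_ginis(signatures.housekeeping_sets)
    if not marker or not house:
        raise ValueError("no usable marker or housekeeping genes")
    mean_marker = float(np.mean(list(marker.values())))
    mean_house = float(np.mean(list(house.values())))
    return {
        "ragi": mean_marker - mean_house,
        "mean_marker_gini": mean_marker,
        "mean_housekeeping_gini": mean_house,
        "per_gene": {**{f"marker:{n}": g for n, g in marker.items()},
                     **{f"housekeeping:{n}": g for n, g in house.items()}},
    }


def subsampled_ragi(
    matrix: AccessibilityMatrix,
    embedding_sources: Mapping[str, CellEmbeddingSet],
    signatures: SignatureSets,
    methods: Mapping[str, Dict[str, object]],
    n_sub: int = 1000,
    reps: int = 20,
    seed: int = 0,
) -> Dict[str, Dict[str, Dict[str, object]]]:
    """Repeated-subsample RAGI comparison across embedding sources.

    For each rep, sample `n_sub` cells without replacement; cluster every
    embedding source with every method; compute RAGI. Reports mean, sd and
    the raw per-rep scores. The same cell subsample and clustering seed are
    used across sources within a rep, so sources are directly comparable.
    """
    n_cells = matrix.n_cells
    if n_cells < n_sub:
        raise ValueError(f"n_sub={n_sub} exceeds {n_cells} cells")
    for emb in embedding_sources.values():
        if len(emb.barcodes) != n_cells:
            raise ValueError("every embedding source must cover the matrix cells")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    results: Dict[str, Dict[str, Dict[str, object]]] = {
        src: {m: {"scores": []} for m in methods} for src in embedding_sources
    }
    for rep in range(reps):
        chosen = np.sort(rng.choice(n_cells, size=n_sub, replace=False))
        sub_matrix = AccessibilityMatrix(
            [matrix.barcodes[i] for i in chosen],
            matrix.regions,
            matrix.entries[chosen],
        )
        for src, emb in embedding_sources.items():
            sub_emb = CellEmbeddingSet(
                [emb.barcodes[i] for i in chosen],
                emb.vectors[chosen],
                emb.coverage[chosen],
            )
            for mname, mparams in methods.items():
                params = dict(mparams)
                method = params.pop("method", mname)
                assignment = cluster(sub_emb, method, seed=seed + rep, **params)
                score = ragi(sub_matrix, assignment, signatures)["ragi"]
                results[src][mname]["scores"].append(score)
    for src in results:
        for mname in results[src]:
            scores = np.asarray(results[src][mname]["scores"])
            results[src][mname]["mean"] = float(scores.mean())
            results[src][mname]["sd"] = float(scores.std(ddof=1)) if reps > 1 else 0.0
    return results
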