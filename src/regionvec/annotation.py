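"""Reference-based cell-type annotation: k-nearest-neighbour classification
of query cell embeddings against labelled reference embeddings, class
mapping between label vocabularies, and confusion/F1 evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.metrics.pairwise import pairwise_distances

from .pooling import CellEmbeddingSet

logger = logging.getLogger(__name__)

UNLABELED = "unlabeled"


@dataclass
class AnnotationModel:
    reference_vectors: np.ndarray  # n_ref x d
    reference_labels: List[str]
    k_nn: int = 10
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.reference_vectors = np.asarray(self.reference_vectors, dtype=np.float64)
        n_ref = self.reference_vectors.shape[0]
        if len(self.reference_labels) != n_ref:
            raise ValueError("one label required per reference vector")
        if self.k_nn > n_ref:
            raise ValueError(f"k_nn={self.k_nn} exceeds {n_ref} references")


@dataclass
class AnnotationResult:
    barcodes: List[str]
    predicted: List[str]
    confidence: np.ndarray  # majority vote fraction, (0, 1]
    mean_neighbor_distance: np.ndarray
    flags: List[str] = field(default_factory=list)  # "" or "no_coverage"


def fit_annotator(
    reference_embeddings: CellEmbeddingSet,
    labels: Mapping[str, str],
    k_nn: int = 10,
    metric: str = "cosine",
) -> AnnotationModel:
    """Store labelled reference vectors; NaN reference cells are excluded."""
    keep_vecs, keep_labels = [], []
    for i, barcode in enumerate(reference_embeddings.barcodes):
        if reference_embeddings.coverage[i] == 0:
            continue
        if barcode not in labels:
            raise ValueError(f"no label for reference cell {barcode}")
        keep_vecs.append(reference_embeddings.vectors[i])
        keep_labels.append(labels[barcode])
    if len(set(keep_labels)) < 2:
        raise ValueError("reference labels must cover >= 2 classes")
    return AnnotationModel(np.vstack(keep_vecs), keep_labels, k_nn, metric)


def annotate(
    model: AnnotationModel, query_embeddings: CellEmbeddingSet
) -> AnnotationResult:
    """Majority label among the k nearest references per query cell.

    Vote ties go to the label of the single nearest neighbour; distance
    ties go to the lower reference index. NaN query cells are returned
    unlabelled with a flag.
    """
    valid = query_embeddings.valid_mask
    n_query = len(query_embeddings.barcodes)
    predicted = [UNLABELED] * n_query
    confidence = np.zeros(n_query)
    mean_dist = np.full(n_query, np.nan)
    flags = ["no_coverage"] * n_query

    if valid.any():
        dist = pairwise_distances(
            query_embeddings.vectors[valid], model.reference_vectors,
            metric=model.metric,
        )
        # stable argsort: equal distances resolve to the lower reference index
        order = np.argsort(dist, axis=1, kind="stable")[:, : model.k_nn]
        labels = np.asarray(model.reference_labels, dtype=object)
        query_rows = np.flatnonzero(valid)
        for qi, row in zip(query_rows, range(order.shape[0])):
            neigh = order[row]
            neigh_labels = labels[neigh]
            uniq, votes = np.unique(neigh_labels, return_counts=True)
            top = votes.max()
            winners = set(uniq[votes == top])
            if len(winners) > 1:
                label = str(neigh_labels[0])  # nearest neighbour breaks the tie
            else:
                label = str(uniq[votes.argmax()])
            predicted[qi] = label
            confidence[qi] = top / model.k_nn
            mean_dist[qi] = dist[row, neigh].mean()
            flags[qi] = ""
    n_flagged = flags.count("no_coverage")
    if n_flagged:
        logger.warning("%d query cells left unlabeled (no coverage)", n_flagged)
    return AnnotationResult(
        list(query_embeddings.barcodes), predicted, confidence, mean_dist, flags
    )


def map_classes(
    predictions: Sequence[str],
    mapping: Mapping[str, str],
    passthrough: bool = False,
) -> List[str]:
    """Substitute predicted class names through a mapping table. Unmapped
    labels are kept verbatim under passthrough, otherwise an error names
    them."""
    missing = sorted({p for p in predictions if p not in mapping})
    if missing and not passthrough:
        raise ValueError(f"unmapped labels: {missing}")
    return [mapping.get(p, p) for p in predictions]


def evaluate_annotation(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> Dict[str, object]:
    """Confusion matrix and per-class precision/recall/F1 over the barcodes
    present in both tables."""
    shared = [b for b in truth if b in predicted]
    if not shared:
        raise ValueError("no overlapping barcodes between predictions and truth")
    y_true = [truth[b] for b in shared]
    y_pred = [predicted[b] for b in shared]
    classes = sorted(set(y_true) | set(y_pred))
    confusion = _sk_confusion(y_true, y_pred, labels=classes)
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = {
        c: {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(classes, precision, recall, f1, support)
    }
    weights = support / support.sum()
    return {
        "classes": classes,
        "confusion": confusion,
        "per_class": per_class,
        "macro_f1": float(f1.mean()),
        "weighted_f1": float((f1 * weights).sum()),
        "n": len(shared),
    }
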