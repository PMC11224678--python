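"""Skip-gram with negative sampling (SGNS) over shuffled region documents.

The training objective for an observed (target, context) pair with k noise
words is

    L = -log sigma(u_ctx . v_tgt) - sum_i log sigma(-u_neg_i . v_tgt)

minimized by SGD with a per-epoch exponential learning-rate schedule
(lr_e = lr0 * decay**e). Documents are re-shuffled every epoch with a fresh
permutation seeded from (seed, epoch, document index), so the whole run is
bit-reproducible in the single-threaded reference mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import Corpus, epoch_rng, word_to_region
from .io_formats import GenomicRegion, ModelBundle

logger = logging.getLogger(__name__)

try:  # optional fast path; the numpy fallback is the reference implementation
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class TrainingConfig:
    dimension: int = 100
    window: int = 5
    epochs: int = 100
    decay: float = 0.95
    initial_lr: float = 0.025
    negatives: int = 5
    min_count: int = 1
    seed: int = 0
    noise_exponent: float = 0.75
    use_numba: bool = True

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")


@dataclass
class EmbeddingTables:
    input_vectors: np.ndarray
    context_vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.input_vectors.shape != self.context_vectors.shape:
            raise ValueError("tables must have equal shape")


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Dict[str, int]:
    """Index words occurring in >= min_count documents, ordered by
    descending document count with lexicographic tie-break."""
    kept = [
        (w, c) for w, c in corpus.vocabulary_counts.items() if c >= min_count
    ]
    if not kept:
        raise ValueError(
            f"empty vocabulary at min_count={min_count} "
            f"({len(corpus.vocabulary_counts)} words observed)"
        )
    kept.sort(key=lambda wc: (-wc[1], wc[0]))
    return {w: i for i, (w, _) in enumerate(kept)}


def noise_distribution(
    counts: np.ndarray, noise_exponent: float = 0.75
) -> np.ndarray:
    """p(w) proportional to count(w)**noise_exponent, normalized."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts <= 0).any():
        raise ValueError("all counts must be > 0")
    weights = counts ** noise_exponent
    return weights / weights.sum()


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def sgns_loss(
    v_target: np.ndarray, u_pos: np.ndarray, u_negs: np.ndarray
) -> float:
    """Negative-sampling loss for one pair; u_negs is (k, d)."""
    v_target = np.asarray(v_target, dtype=np.float64)
    u_negs = np.atleast_2d(np.asarray(u_negs, dtype=np.float64))
    pos = _log_sigmoid(float(np.dot(u_pos, v_target)))
    neg = _log_sigmoid(-(u_negs @ v_target)).sum()
    return float(-pos - neg)


def sgns_step(
    tables: EmbeddingTables,
    target_idx: int,
    context_idx: int,
    negatives: Sequence[int],
    lr: float,
) -> EmbeddingTables:
    """One in-place SGD step on sgns_loss w.r.t. the target input vector,
    the positive context vector and each negative context vector."""
    if lr < 0:
        raise ValueError("lr must be >= 0")
    inp, ctx = tables.input_vectors, tables.context_vectors
    v = inp[target_idx]
    rows = np.concatenate(([context_idx], np.asarray(negatives, dtype=np.int64)))
    u = ctx[rows]  # (k+1, d) copy
    f = u @ v
    sig = 1.0 / (1.0 + np.exp(-np.clip(f, -500, 500)))
    g = sig.copy()
    g[0] -= 1.0  # d L / d f: sigma(f)-1 for positive, sigma(f) for negatives
    grad_v = g @ u
    # repeated negative indices must accumulate
    for i, r in enumerate(rows):
        ctx[r] -= lr * g[i] * v
    inp[target_idx] = v - lr * grad_v
    return tables


if _HAVE_NUMBA:

    @_njit(cache=False, fastmath=False)
    def _sgd_pairs_numba(inp, ctx, targets, contexts, negs, lr):  # pragma: no cover
        n_pairs, k = negs.shape
        d = inp.shape[1]
        for p in range(n_pairs):
            t = targets[p]
            grad_v = np.zeros(d)
            for j in range(k + 1):
                r = contexts[p] if j == 0 else negs[p, j - 1]
                f = 0.0
                for a in range(d):
                    f += ctx[r, a] * inp[t, a]
                if f >= 0.0:
                    sig = 1.0 / (1.0 + np.exp(-f))
                else:
                    e = np.exp(f)
                    sig = e / (1.0 + e)
                g = sig - 1.0 if j == 0 else sig
                for a in range(d):
                    grad_v[a] += g * ctx[r, a]
                    ctx[r, a] -= lr * g * inp[t, a]
            for a in range(d):
                inp[t, a] -= lr * grad_v[a]


def _sgd_pairs_numpy(inp, ctx, targets, contexts, negs, lr):
    tables = EmbeddingTables(inp, ctx)
    for p in range(len(targets)):
        sgns_step(tables, targets[p], contexts[p], negs[p], lr)


def _doc_pairs(
    idx: np.ndarray, windows: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """All (target, context) index pairs for one shuffled document given the
    per-position effective window sizes."""
    targets: List[int] = []
    contexts: List[int] = []
    n = len(idx)
    for t in range(n):
        b = windows[t]
        lo = t - b if t - b > 0 else 0
        hi = t + b + 1 if t + b + 1 < n else n
        for c in range(lo, hi):
            if c != t:
                targets.append(idx[t])
                contexts.append(idx[c])
    return (
        np.asarray(targets, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )


def _sample_noise(
    rng: np.random.Generator, cumulative: np.ndarray, size: int
) -> np.ndarray:
    return np.searchsorted(cumulative, rng.random(size), side="right").astype(np.int64)


def train(
    corpus: Corpus,
    config: TrainingConfig,
    consensus: Optional[List[GenomicRegion]] = None,
) -> ModelBundle:
    """Train region embeddings over the shuffled corpus.

    Every epoch re-shuffles each document (fresh permutation from
    (seed, epoch, doc index)), draws a per-position effective window
    uniform in {1..window}, and applies one SGD step per (target, context)
    pair with `negatives` noise words drawn from the unigram^exponent
    distribution; a noise draw equal to the positive context is resampled.
    """
    if not corpus.documents:
        raise ValueError("empty corpus")
    vocabulary = build_vocabulary(corpus, config.min_count)
    n_vocab = len(vocabulary)
    words = [None] * n_vocab
    for w, i in vocabulary.items():
        words[i] = w
    counts = np.array(
        [corpus.vocabulary_counts[w] for w in words], dtype=np.float64
    )
    noise = noise_distribution(counts, config.noise_exponent)
    cumulative = np.cumsum(noise)
    cumulative[-1] = 1.0  # guard against fp drift

    init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    d = config.dimension
    inp = (init_rng.random((n_vocab, d)) - 0.5) / d
    ctx = np.zeros((n_vocab, d))

    # per-document vocabulary index arrays, computed once
    doc_idx: List[np.ndarray] = []
    for doc in corpus.documents:
        doc_idx.append(
            np.array(
                [vocabulary[w] for w in doc.words if w in vocabulary],
                dtype=np.int64,
            )
        )

    use_numba = _HAVE_NUMBA and config.use_numba
    sgd = _sgd_pairs_numba if use_numba else _sgd_pairs_numpy
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    k = config.negatives
    total_pairs = 0
    for epoch in range(config.epochs):
        lr = config.initial_lr * config.decay ** epoch
        for di in range(len(doc_idx)):
            idx = doc_idx[di]
            n = len(idx)
            if n < 2:
                continue
            perm = epoch_rng(config.seed, epoch, di).permutation(n)
            shuffled = idx[perm]
            windows = master.integers(1, config.window + 1, size=n)
            targets, contexts = _doc_pairs(shuffled, windows)
            if len(targets) == 0:
                continue
            negs = _sample_noise(master, cumulative, len(targets) * k).reshape(
                len(targets), k
            )
            bad = negs == contexts[:, None]
            while bad.any():
                negs[bad] = _sample_noise(master, cumulative, int(bad.sum()))
                bad = negs == contexts[:, None]
            sgd(inp, ctx, targets, contexts, negs, lr)
            total_pairs += len(targets)
    logger.info(
        "trained %d epochs over %d documents (%d pairs total)",
        config.epochs, len(corpus.documents), total_pairs,
    )

    if consensus is None:
        consensus = [word_to_region(w) for w in words]
    metadata = {
        "dimension": config.dimension,
        "window": config.window,
        "epochs": config.epochs,
        "decay": config.decay,
        "initial_lr": config.initial_lr,
        "negatives": config.negatives,
        "min_count": config.min_count,
        "noise_exponent": config.noise_exponent,
        "seed": config.seed,
        "consensus_region_count": len(consensus),
    }
    return ModelBundle(vocabulary, inp, ctx, consensus, metadata)


def make_config(**kwargs) -> TrainingConfig:
    """Convenience constructor used by the CLI."""
    return replace(TrainingConfig(), **kwargs)
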