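"""On-disk artifacts: MTX matrices with BED/TSV sidecars, BED region sets,
model bundles (vector tables + consensus + metadata), and label tables.

Coordinates are BED convention throughout: 0-based, half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_VECTORS_FILE = "vectors.tsv"
_CONTEXT_VECTORS_FILE = "context_vectors.tsv"
_CONSENSUS_FILE = "consensus.bed"
_METADATA_FILE = "metadata.txt"

# decimal text round trip at >= 8 significant digits; repr of float64 is exact
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A chromosome interval, 0-based half-open — the atomic 'word'."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class AccessibilityMatrix:
    """Sparse cells x regions matrix of non-negative counts."""

    barcodes: List[str]
    regions: List[GenomicRegion]
    entries: sp.csr_matrix

    def __post_init__(self) -> None:
        self.entries = sp.csr_matrix(self.entries)
        n, m = self.entries.shape
        if len(self.barcodes) != n:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n} matrix rows"
            )
        if len(self.regions) != m:
            raise ValueError(
                f"{len(self.regions)} regions for {m} matrix columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.entries.nnz and self.entries.data.min() < 0:
            raise ValueError("matrix values must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]

    @property
    def n_regions(self) -> int:
        return self.entries.shape[1]

    def binarized(self) -> sp.csr_matrix:
        """Signal pattern: 1 where entry > 0."""
        out = self.entries.copy()
        out.data = np.ones_like(out.data)
        out.sort_indices()
        return out


@dataclass
class ModelBundle:
    """Trained region-embedding artifact: vocabulary, paired vector tables,
    consensus regions and training metadata."""

    vocabulary: Dict[str, int]  # word -> row index
    input_vectors: np.ndarray  # |V| x d
    context_vectors: np.ndarray  # |V| x d
    consensus: List[GenomicRegion]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input_vectors = np.asarray(self.input_vectors, dtype=np.float64)
        self.context_vectors = np.asarray(self.context_vectors, dtype=np.float64)
        if self.input_vectors.shape != self.context_vectors.shape:
            raise ValueError("input/context vector tables must have equal shape")
        if len(self.vocabulary) != self.input_vectors.shape[0]:
            raise ValueError("vocabulary size does not match vector table rows")
        d = self.input_vectors.shape[1]
        md = int(self.metadata.get("dimension", d))
        if md != d:
            raise ValueError(f"metadata dimension {md} != table width {d}")
        self.metadata.setdefault("dimension", d)

    @property
    def dimension(self) -> int:
        return self.input_vectors.shape[1]

    @property
    def words(self) -> List[str]:
        out = [""] * len(self.vocabulary)
        for w, i in self.vocabulary.items():
            out[i] = w
        return out


def read_bed(path: str) -> List[GenomicRegion]:
    """Read a BED3+ file; extra columns are ignored."""
    regions: List[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                regions.append(GenomicRegion(fields[0], start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_barcodes(path: str) -> List[str]:
    """One identifier per line; only the first tab-separated field is kept."""
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_barcodes(barcodes: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for b in barcodes:
            fh.write(b + "\n")


def read_mtx(
    matrix_path: str, barcodes_path: str, regions_path: str
) -> AccessibilityMatrix:
    """Read a MatrixMarket coordinate matrix with barcode/region sidecars.

    Canonical orientation is cells x regions. If the MTX header instead
    matches (regions, cells), the matrix is transposed and a notice logged.
    Never densifies: memory scales with nnz.
    """
    barcodes = read_barcodes(barcodes_path)
    regions = read_bed(regions_path)
    mat = scipy.io.mmread(matrix_path)
    mat = sp.coo_matrix(mat)
    n, m = mat.shape
    nb, nr = len(barcodes), len(regions)
    if (n, m) == (nb, nr):
        pass
    elif (n, m) == (nr, nb) and nb != nr:
        logger.info(
            "MTX %s is %d x %d (regions x cells); transposing to cells x regions",
            matrix_path, n, m,
        )
        mat = mat.T
    else:
        raise ValueError(
            f"MTX dimensions {n} x {m} do not match sidecars: "
            f"{nb} barcodes, {nr} regions"
        )
    return AccessibilityMatrix(barcodes, regions, sp.csr_matrix(mat))


def write_mtx(
    matrix: AccessibilityMatrix,
    matrix_path: str,
    barcodes_path: str,
    regions_path: str,
) -> None:
    scipy.io.mmwrite(matrix_path, sp.coo_matrix(matrix.entries))
    write_barcodes(matrix.barcodes, barcodes_path)
    write_bed(matrix.regions, regions_path)


def _parse_word(word: str) -> GenomicRegion:
    # split on the LAST two underscores so "chr1_gl000191_10_20" parses
    head, _, end_s = word.rpartition("_")
    chrom, _, start_s = head.rpartition("_")
    if not chrom:
        raise ValueError(f"word {word!r} is not of the form chrom_start_end")
    try:
        return GenomicRegion(chrom, int(start_s), int(end_s))
    except ValueError as exc:
        raise ValueError(f"word {word!r} does not parse to a region: {exc}") from exc


def _read_vectors_tsv(path: str, dimension: int) -> tuple[List[str], np.ndarray]:
    words: List[str] = []
    rows: List[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) - 1 != dimension:
                raise ValueError(
                    f"{path}:{lineno}: expected {dimension} values, "
                    f"got {len(fields) - 1}"
                )
            _parse_word(fields[0])  # validates word shape
            words.append(fields[0])
            rows.append(np.array([float(x) for x in fields[1:]]))
    return words, np.vstack(rows) if rows else np.empty((0, dimension))


def _write_vectors_tsv(path: str, words: Sequence[str], table: np.ndarray) -> None:
    with open(path, "w") as fh:
        for w, row in zip(words, table):
            fh.write(w + "\t" + "\t".join(_FLOAT_FMT % x for x in row) + "\n")


def save_model(bundle: ModelBundle, directory: str) -> None:
    """Write a model bundle directory: vectors TSV, context-vectors TSV,
    consensus BED and a key=value metadata file."""
    os.makedirs(directory, exist_ok=True)
    words = bundle.words
    _write_vectors_tsv(os.path.join(directory, _VECTORS_FILE), words, bundle.input_vectors)
    _write_vectors_tsv(
        os.path.join(directory, _CONTEXT_VECTORS_FILE), words, bundle.context_vectors
    )
    write_bed(bundle.consensus, os.path.join(directory, _CONSENSUS_FILE))
    meta = dict(bundle.metadata)
    meta.setdefault("dimension", bundle.dimension)
    meta.setdefault("consensus_region_count", len(bundle.consensus))
    with open(os.path.join(directory, _METADATA_FILE), "w") as fh:
        for k in sorted(meta):
            fh.write(f"{k}={meta[k]}\n")


def _coerce_meta(value: str) -> object:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def load_model(directory: str) -> ModelBundle:
    metadata: Dict[str, object] = {}
    with open(os.path.join(directory, _METADATA_FILE)) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            k, v = line.split("=", 1)
            metadata[k] = _coerce_meta(v)
    d = int(metadata["dimension"])
    words, inp = _read_vectors_tsv(os.path.join(directory, _VECTORS_FILE), d)
    cwords, ctx = _read_vectors_tsv(os.path.join(directory, _CONTEXT_VECTORS_FILE), d)
    if words != cwords:
        raise ValueError("vectors and context-vectors list different words")
    consensus = read_bed(os.path.join(directory, _CONSENSUS_FILE))
    vocabulary = {w: i for i, w in enumerate(words)}
    if len(vocabulary) != len(words):
        raise ValueError("duplicate words in vectors file")
    return ModelBundle(vocabulary, inp, ctx, consensus, metadata)


def read_labels(path: str) -> Dict[str, str]:
    """Newline-delimited label table: barcode<TAB>label."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected barcode<TAB>label")
            out[fields[0]] = fields[1]
    return out


def write_labels(labels: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for barcode, label in labels.items():
            fh.write(f"{barcode}\t{label}\n")


def read_embeddings_tsv(path: str) -> tuple[List[str], np.ndarray]:
    """Barcode + d floats per line; NaN rows mark zero-coverage cells."""
    barcodes: List[str] = []
    rows: List[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            barcodes.append(fields[0])
            rows.append(np.array([float(x) for x in fields[1:]]))
    return barcodes, np.vstack(rows)


def write_embeddings_tsv(barcodes: Sequence[str], vectors: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        for b, row in zip(barcodes, vectors):
            fh.write(b + "\t" + "\t".join(_FLOAT_FMT % x for x in row) + "\n")
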