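"""Synthetic accessibility matrices with planted cell-type structure.

Regions are laid out as fixed-width, non-overlapping intervals on synthetic
chromosomes. Each cell type owns a disjoint block of signature regions
sampled at high probability; a housekeeping block is uniformly accessible
across types; everything else is low-probability background. The generator
also provides a coordinate-jitter operator for exercising overlap mapping
and an exact-count dropout operator for data-loss experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import scipy.sparse as sp

from .cluster_metrics import SignatureSets
from .io_formats import AccessibilityMatrix, GenomicRegion

REGION_WIDTH = 500
REGION_GAP = 1000
REGIONS_PER_CHROM = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    n_types: int = 5
    cells_per_type: int = 100
    n_regions: int = 2000
    signature_size: int = 50
    housekeeping_size: int = 50
    p_high: float = 0.3
    p_low: float = 0.01
    p_house: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.cells_per_type < 1:
            raise ValueError("need >= 1 type and >= 1 cell per type")
        reserved = self.n_types * self.signature_size + self.housekeeping_size
        if reserved > self.n_regions:
            raise ValueError(
                f"{reserved} signature+housekeeping regions exceed "
                f"{self.n_regions} total regions"
            )
        if not (0 <= self.p_low < self.p_high <= 1):
            raise ValueError("need 0 <= p_low < p_high <= 1")
        if not (0 <= self.p_house <= 1):
            raise ValueError("p_house must be in [0, 1]")


def region_layout(n_regions: int) -> List[GenomicRegion]:
    """Non-overlapping fixed-width regions on chromosomes chrS1, chrS2, ..."""
    regions = []
    for j in range(n_regions):
        chrom = f"chrS{j // REGIONS_PER_CHROM + 1}"
        start = (j % REGIONS_PER_CHROM) * (REGION_WIDTH + REGION_GAP)
        regions.append(GenomicRegion(chrom, start, start + REGION_WIDTH))
    return regions


def generate(
    spec: SyntheticSpec,
) -> Tuple[AccessibilityMatrix, Dict[str, str], SignatureSets]:
    """Sample a cells x regions binary matrix with planted types.

    Entry (cell, region) ~ Bernoulli(p) with p = p_high on the cell type's
    own signature block, p_house on the housekeeping block and p_low
    elsewhere. Returns the matrix, barcode -> type labels and the
    marker/housekeeping signature sets. Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    sig, house = spec.signature_size, spec.housekeeping_size
    n_cells = spec.n_types * spec.cells_per_type
    regions = region_layout(spec.n_regions)

    probs = np.full((spec.n_types, spec.n_regions), spec.p_low)
    marker_sets: Dict[str, set] = {}
    for t in range(spec.n_types):
        block = np.arange(t * sig, (t + 1) * sig)
        probs[t, block] = spec.p_high
        marker_sets[f"type{t}"] = set(int(i) for i in block)
    house_block = np.arange(spec.n_types * sig, spec.n_types * sig + house)
    probs[:, house_block] = spec.p_house
    housekeeping_sets = {"housekeeping": set(int(i) for i in house_block)}

    cell_types = np.repeat(np.arange(spec.n_types), spec.cells_per_type)
    dense = rng.random((n_cells, spec.n_regions)) < probs[cell_types]
    matrix = AccessibilityMatrix(
        [f"cell_{i:05d}" for i in range(n_cells)],
        regions,
        sp.csr_matrix(dense.astype(np.float64)),
    )
    labels = {
        b: f"type{t}" for b, t in zip(matrix.barcodes, cell_types)
    }
    return matrix, labels, SignatureSets(marker_sets, housekeeping_sets)


def apply_dropout(
    matrix: AccessibilityMatrix, rate: float, seed: int
) -> AccessibilityMatrix:
    """Zero out exactly round(rate * nnz) non-zero entries, chosen uniformly
    without replacement. Zeros are never touched; deterministic under seed."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    coo = sp.coo_matrix(matrix.entries)
    nnz = coo.nnz
    n_drop = int(round(rate * nnz))
    if n_drop == 0:
        return AccessibilityMatrix(
            list(matrix.barcodes), list(matrix.regions), matrix.entries.copy()
        )
    rng = np.random.default_rng(seed)
    drop = rng.choice(nnz, size=n_drop, replace=False)
    keep = np.ones(nnz, dtype=bool)
    keep[drop] = False
    out = sp.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
    )
    return AccessibilityMatrix(list(matrix.barcodes), list(matrix.regions), out)


def jitter_regions(
    regions: List[GenomicRegion], max_shift: int, seed: int, min_gap: int = None
) -> List[GenomicRegion]:
    """Shift every region by an integer uniform in [-max_shift, +max_shift],
    preserving width. Requires inter-region gaps >= 2 * max_shift on each
    chromosome so a jittered region can only overlap its origin."""
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    required_gap = 2 * max_shift if min_gap is None else min_gap
    by_chrom: Dict[str, List[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            gap = b.start - a.end
            if gap < required_gap:
                raise ValueError(
                    f"gap {gap} bp between {chrom}:{a.start}-{a.end} and "
                    f"{chrom}:{b.start}-{b.end} is below {required_gap} bp"
                )
    rng = np.random.default_rng(seed)
    shifts = rng.integers(-max_shift, max_shift + 1, size=len(regions))
    out = []
    for r, s in zip(regions, shifts):
        start = max(0, r.start + int(s))
        out.append(GenomicRegion(r.chrom, start, start + r.width))
    return out
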