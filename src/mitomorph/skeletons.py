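"""Skeleton-based length measurement of mitochondrial objects.

Each connected object is thinned to a one-pixel-wide medial curve by
topology-preserving Zhang–Suen thinning, and its length is the sum of the
unique 8-adjacent skeleton-pixel pair distances: 1 pixel for orthogonal
neighbours, sqrt(2) for diagonal neighbours, scaled by the pixel size.
This edge-sum rule is less biased for oblique filaments than a raw pixel
count (which is nevertheless exported for comparability). A punctum
collapses to (near) a single pixel, so fragmented mitochondria contribute
near-zero length. "Average mitochondrial length" of a cell is the
unweighted mean over its connected objects, each measured as whole-skeleton
total length (not per branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .fields import LabelMap

__all__ = [
    "SkeletonMeasure",
    "skeletonize_object",
    "skeleton_length",
    "count_branchpoints",
    "measure_skeletons",
    "mean_length_per_cell",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SkeletonMeasure:
    """Skeleton statistics of one mitochondrial object."""

    object_id: int
    skeleton_pixels: int
    length_um: float
    n_branchpoints: int

    def __post_init__(self) -> None:
        if self.object_id <= 0:
            raise ValueError("object_id must be positive")
        if self.skeleton_pixels < 1:
            raise ValueError("a non-empty object has at least one skeleton pixel")
        if self.length_um < 0:
            raise ValueError("length cannot be negative")


def skeletonize_object(mask: np.ndarray) -> np.ndarray:
    """Thin a binary object to its (at most) 1-px-wide skeleton.

    Topology-preserving Zhang–Suen thinning; the skeleton is a subset of
    the mask and the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    return skeletonize(mask)


def _adjacency_counts(skeleton: np.ndarray) -> tuple[int, int]:
    """(orthogonal, diagonal) unique adjacent skeleton-pixel pair counts."""
    s = np.asarray(skeleton, dtype=bool)
    # each unordered pair counted once: east, south, south-east, south-west
    orth = int((s[:, :-1] & s[:, 1:]).sum()) + int((s[:-1, :] & s[1:, :]).sum())
    diag = int((s[:-1, :-1] & s[1:, 1:]).sum()) + int((s[:-1, 1:] & s[1:, :-1]).sum())
    return orth, diag


def skeleton_length(skeleton: np.ndarray, pixel_size_um: float) -> float:
    """Geodesic edge-sum length of a 1-px-wide skeleton, in µm.

    Sums 1 per orthogonally adjacent pair and sqrt(2) per diagonally
    adjacent pair of skeleton pixels (each unordered pair once), times the
    pixel size. A single isolated pixel has length 0.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("cannot measure an empty skeleton")
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    orth, diag = _adjacency_counts(skeleton)
    return (orth + diag * _SQRT2) * pixel_size_um


def count_branchpoints(skeleton: np.ndarray) -> int:
    """Skeleton pixels with three or more skeleton neighbours (8-connected)."""
    s = np.asarray(skeleton, dtype=bool)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbours = ndimage.convolve(s.astype(int), kernel, mode="constant")
    return int(((neighbours >= 3) & s).sum())


def measure_skeletons(
    mito_labels: LabelMap, pixel_size_um: float
) -> list[SkeletonMeasure]:
    """Skeletonize and measure every labeled mitochondrial object."""
    measures: list[SkeletonMeasure] = []
    if mito_labels.n_objects == 0:
        return measures
    slices = ndimage.find_objects(mito_labels.labels)
    for oid, sl in enumerate(slices, start=1):
        mask = mito_labels.labels[sl] == oid
        skel = skeletonize_object(mask)
        if not skel.any():
            # thinning of a tiny object may erase it entirely; treat as a point
            measures.append(SkeletonMeasure(oid, 1, 0.0, 0))
            continue
        measures.append(
            SkeletonMeasure(
                object_id=oid,
                skeleton_pixels=int(skel.sum()),
                length_um=skeleton_length(skel, pixel_size_um),
                n_branchpoints=count_branchpoints(skel),
            )
        )
    return measures


def mean_length_per_cell(
    measures: list[SkeletonMeasure],
    cell_of: dict[int, int | None],
    cell_ids: list[int] | None = None,
) -> dict[int, float]:
    """Unweighted mean skeleton length (µm) per cell.

    ``cell_of`` maps object_id → cell_id (None = unassigned, excluded).
    Every object_id in ``cell_of`` must have a measure. Cells listed in
    ``cell_ids`` that own no objects are emitted with NaN, never zero.
    """
    by_id = {m.object_id: m for m in measures}
    missing = [oid for oid in cell_of if oid not in by_id]
    if missing:
        raise KeyError(f"objects without a skeleton measure: {sorted(missing)}")
    sums: dict[int, list[float]] = {}
    for oid, cid in cell_of.items():
        if cid is None:
            continue
        sums.setdefault(int(cid), []).append(by_id[oid].length_um)
    out = {cid: float(np.mean(v)) for cid, v in sums.items()}
    for cid in cell_ids or []:
        out.setdefault(int(cid), float("nan"))
    return out
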