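"""Nucleus and single-cell segmentation.

The scheme follows the classic primary/secondary object design: nuclei are
detected first on the nuclear channel by two-class Otsu thresholding, then
each cell body is delineated by expanding every nucleus through the
cell-stain foreground until it meets its neighbours — a seeded geodesic
propagation in which each foreground pixel joins the nucleus it can reach
by the shortest path that stays inside the foreground. Every resulting
cell therefore contains exactly one nucleus.

Geodesic distance is defined canonically as ``n_orth + sqrt(2) * n_diag``
over 8-connected steps, with the two integer step counts carried through
the search so that distance comparisons are exact (no accumulated
floating-point drift; distinct step-count pairs can never be truly equal).
Ties between nuclei at exactly equal distance go to the lower label.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
from scipy import ndimage

from .fields import LabelMap, relabel_consecutive

__all__ = [
    "otsu_threshold",
    "segment_nuclei",
    "segment_cells",
    "propagate_labels",
]

#: 8-connectivity structuring element used for every component labeling step.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

_SQRT2 = math.sqrt(2.0)
# (drow, dcol, is_diagonal)
_NEIGHBORS = [
    (-1, -1, True), (-1, 0, False), (-1, 1, True),
    (0, -1, False), (0, 1, False),
    (1, -1, True), (1, 0, False), (1, 1, True),
]


def _between_class_variance(counts: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Between-class variance for each cut 'after value k' of a histogram.

    Entry k is the variance of the split {values <= values[k]} vs
    {values > values[k]}; the last entry (empty upper class) is 0.
    """
    counts = counts.astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    sum0 = np.cumsum(counts * values)
    mu_total = sum0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0 / w0
        mu1 = (mu_total - sum0) / w1
    sigma = w0 * w1 * (mu0 - mu1) ** 2
    sigma[~np.isfinite(sigma)] = 0.0
    return sigma


def otsu_threshold(image: np.ndarray) -> float:
    """Two-class Otsu threshold of an intensity image.

    Returns the threshold ``t`` maximizing the between-class variance of the
    split ``{pixels <= t}`` / ``{pixels > t}``; ties are broken by the
    smallest ``t``. Integer images with values in [0, 255] are searched
    exactly over the values present; other data are histogrammed into 256
    uniform bins between the image minimum and maximum and the threshold is
    the maximizing bin's upper edge (so foreground = ``image > t`` excludes
    the bin itself).

    Raises
    ------
    ValueError
        If the image is constant (no two classes to separate).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    lo = image.min()
    hi = image.max()
    if lo == hi:
        raise ValueError(
            f"constant image (all pixels = {lo}): no separable intensity classes"
        )
    if np.issubdtype(image.dtype, np.integer) and lo >= 0 and hi <= 255:
        values, counts = np.unique(image, return_counts=True)
        sigma = _between_class_variance(counts, values.astype(np.float64))
        # last split leaves the upper class empty; never a valid threshold
        best = int(np.argmax(sigma[:-1]))
        return float(values[best])
    nbins = 256
    counts, edges = np.histogram(image, bins=nbins, range=(float(lo), float(hi)))
    centers = (edges[:-1] + edges[1:]) / 2.0
    sigma = _between_class_variance(counts, centers)
    best = int(np.argmax(sigma[:-1]))
    return float(edges[best + 1])


def segment_nuclei(
    nuclear_channel: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 20.0,
) -> LabelMap:
    """Detect nuclei: Otsu foreground, hole filling, 8-connected components,
    removal of components smaller than ``min_area_um2`` (debris), consecutive
    relabeling. Nuclei touching the field border are kept (the border policy
    applies to cells, not their seeds)."""
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    t = otsu_threshold(nuclear_channel)
    fg = np.asarray(nuclear_channel) > t
    fg = ndimage.binary_fill_holes(fg)
    labels, _ = ndimage.label(fg, structure=STRUCTURE_8)
    min_px = min_area_um2 / (pixel_size_um ** 2)
    areas = np.bincount(labels.ravel())
    too_small = np.flatnonzero(areas < min_px)
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    return LabelMap(relabel_consecutive(labels))


def propagate_labels(foreground: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Assign every foreground pixel to its geodesically nearest seed label.

    Multi-source Dijkstra on the 8-connected grid restricted to
    ``foreground | seeds``, with step weights 1 (orthogonal) and sqrt(2)
    (diagonal). The per-pixel winner is the seed with the smallest geodesic
    distance; exact ties go to the lower seed label. Distances are compared
    through their integer step counts, which makes the assignment exact and
    identical to per-seed shortest-path computation. Foreground pixels with
    no geodesic path to any seed stay background.

    Connected components of the domain containing a single seed label are
    assigned wholesale (the nearest seed is the only reachable one); the
    heap search runs only inside components shared by several seeds.
    """
    foreground = np.asarray(foreground, dtype=bool)
    seeds = np.asarray(seeds)
    if foreground.shape != seeds.shape:
        raise ValueError("foreground and seeds must share shape")
    domain = foreground | (seeds > 0)
    out = np.zeros(domain.shape, dtype=np.int32)
    comp, n_comp = ndimage.label(domain, structure=STRUCTURE_8)
    if n_comp == 0:
        return out
    comp_slices = ndimage.find_objects(comp)
    for ci, sl in enumerate(comp_slices, start=1):
        in_comp = comp[sl] == ci
        comp_seeds = np.where(in_comp, seeds[sl], 0)
        labels_here = np.unique(comp_seeds)
        labels_here = labels_here[labels_here > 0]
        if labels_here.size == 0:
            continue
        if labels_here.size == 1:
            out[sl][in_comp] = labels_here[0]
        else:
            assigned = _dijkstra_assign(in_comp, comp_seeds)
            out[sl][in_comp] = assigned[in_comp]
    return out


def _dijkstra_assign(domain: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Exact lexicographic multi-source Dijkstra on one domain."""
    nrow, ncol = domain.shape
    best_key = np.full(domain.shape, np.inf)
    best_label = np.zeros(domain.shape, dtype=np.int32)
    settled = np.zeros(domain.shape, dtype=bool)

    heap: list[tuple[float, int, int, int, int, int]] = []
    seed_rows, seed_cols = np.nonzero(seeds > 0)
    for r, c in zip(seed_rows.tolist(), seed_cols.tolist()):
        lab = int(seeds[r, c])
        best_key[r, c] = 0.0
        best_label[r, c] = lab
        heapq.heappush(heap, (0.0, lab, 0, 0, r, c))

    out = np.zeros(domain.shape, dtype=np.int32)
    while heap:
        key, lab, a, b, r, c = heapq.heappop(heap)
        if settled[r, c]:
            continue
        if key != best_key[r, c] or lab != best_label[r, c]:
            continue
        settled[r, c] = True
        out[r, c] = lab
        for dr, dc, diag in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if nr < 0 or nr >= nrow or nc < 0 or nc >= ncol:
                continue
            if not domain[nr, nc] or settled[nr, nc]:
                continue
            na, nb = (a, b + 1) if diag else (a + 1, b)
            nkey = na + nb * _SQRT2  # canonical: recomputed from step counts
            cur_key = best_key[nr, nc]
            if nkey < cur_key or (nkey == cur_key and lab < best_label[nr, nc]):
                best_key[nr, nc] = nkey
                best_label[nr, nc] = lab
                heapq.heappush(heap, (nkey, lab, na, nb, nr, nc))
    return out


def segment_cells(
    cell_channel: np.ndarray,
    nuclei: LabelMap,
    remove_border: bool = True,
) -> LabelMap:
    """Expand nuclei to cell bodies within the cell-stain foreground.

    Cell foreground is the Otsu foreground of ``cell_channel`` united with
    all nucleus pixels (a nucleus always belongs to its cell even if the
    cytoplasmic stain is dim there). Each foreground pixel is assigned to
    the geodesically nearest nucleus (see :func:`propagate_labels`). Cells
    touching the field border are removed when ``remove_border`` (partial
    cells bias per-cell statistics) and survivors are relabeled 1..n in
    increasing order of their nucleus label.
    """
    if nuclei.n_objects == 0:
        raise ValueError("cannot segment cells: nuclei label map is empty")
    cell_channel = np.asarray(cell_channel)
    if cell_channel.shape != nuclei.shape:
        raise ValueError("cell channel and nuclei label map must share shape")
    t = otsu_threshold(cell_channel)
    fg = cell_channel > t
    assigned = propagate_labels(fg, nuclei.labels)
    if remove_border:
        border_labels = np.unique(
            np.concatenate(
                [assigned[0, :], assigned[-1, :], assigned[:, 0], assigned[:, -1]]
            )
        )
        border_labels = border_labels[border_labels > 0]
        assigned[np.isin(assigned, border_labels)] = 0
    return LabelMap(relabel_consecutive(assigned))
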