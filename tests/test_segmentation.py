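"""Otsu thresholding and nucleus/cell segmentation against brute-force
oracles and generator truth."""

import heapq
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from mitomorph import (
    LabelMap,
    otsu_threshold,
    propagate_labels,
    segment_cells,
    segment_nuclei,
)
from mitomorph.synthesis import render_punctum

SQRT2 = math.sqrt(2.0)


# ------------------------------------------------------------------ oracles

def otsu_brute_force(image: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over t in 0..255,
    smallest-t tie-break. Independent of the implementation under test."""
    flat = image.ravel().astype(np.float64)
    best_t, best_sigma = None, -1.0
    for t in range(256):
        low = flat[flat <= t]
        high = flat[flat > t]
        if len(low) == 0 or len(high) == 0:
            continue
        w0, w1 = len(low), len(high)
        sigma = w0 * w1 * (low.mean() - high.mean()) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, t
    return best_t


def geodesic_assign_brute(domain: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Per-seed single-source Dijkstra, then per-pixel argmin with
    lower-label tie-break. Distances carried as (orthogonal, diagonal)
    step counts with the canonical key a + b*sqrt(2)."""
    domain = domain | (seeds > 0)
    labels = np.unique(seeds)
    labels = labels[labels > 0]
    nrow, ncol = domain.shape
    best_key = np.full(domain.shape, np.inf)
    best_label = np.zeros(domain.shape, dtype=int)
    for lab in labels:
        key_map = np.full(domain.shape, np.inf)
        heap = []
        for r, c in zip(*np.nonzero(seeds == lab)):
            key_map[r, c] = 0.0
            heapq.heappush(heap, (0.0, 0, 0, int(r), int(c)))
        done = np.zeros(domain.shape, dtype=bool)
        while heap:
            key, a, b, r, c = heapq.heappop(heap)
            if done[r, c]:
                continue
            done[r, c] = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < nrow and 0 <= nc < ncol):
                        continue
                    if not domain[nr, nc] or done[nr, nc]:
                        continue
                    na, nb = (a + 1, b) if dr == 0 or dc == 0 else (a, b + 1)
                    nkey = na + nb * SQRT2
                    if nkey < key_map[nr, nc]:
                        key_map[nr, nc] = nkey
                        heapq.heappush(heap, (nkey, na, nb, nr, nc))
        better = key_map < best_key
        tie = (key_map == best_key) & (key_map < np.inf) & (int(lab) < best_label)
        update = better | tie
        best_key[update] = key_map[update]
        best_label[update] = int(lab)
    best_label[~domain] = 0
    return best_label


# ------------------------------------------------------------------- Otsu

class TestOtsu:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_search_random_8bit(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        assert otsu_threshold(image) == otsu_brute_force(image)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_exhaustive_search_property(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.integers(0, 40, size=(8, 8), dtype=np.uint8)
        if image.min() == image.max():
            return
        assert otsu_threshold(image) == otsu_brute_force(image)

    def test_two_value_image_smallest_t(self):
        image = np.full((10, 10), 200, dtype=np.uint8)
        image[:5] = 10
        t = otsu_threshold(image)
        assert t == 10 == otsu_brute_force(image)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((8, 8), 42, dtype=np.uint8))
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.zeros((8, 8)))

    def test_float_image_cross_check_against_skimage(self, rng):
        """Independent library cross-check: binarizations from the two
        implementations agree on almost all pixels (binning differs)."""
        image = np.concatenate(
            [rng.normal(100, 10, 2000), rng.normal(1000, 50, 500)]
        ).reshape(50, 50)
        t_mine = otsu_threshold(image)
        t_ref = skimage_otsu(image)
        disagree = np.mean((image > t_mine) != (image > t_ref))
        assert disagree < 0.02


# ------------------------------------------------------------------ nuclei

class TestSegmentNuclei:
    def test_recovers_truth_nuclei(self, noiseless_field):
        field, truth = noiseless_field
        result = segment_nuclei(field.nuclear_channel, field.pixel_size_um)
        assert result.n_objects == truth.nucleus_truth_labels.n_objects
        for cid in range(1, truth.nucleus_truth_labels.n_objects + 1):
            t_mask = truth.nucleus_truth_labels.labels == cid
            overlap_labels = result.labels[t_mask]
            lab = np.bincount(overlap_labels).argmax()
            assert lab > 0
            r_mask = result.labels == lab
            iou = (t_mask & r_mask).sum() / (t_mask | r_mask).sum()
            assert iou > 0.8

    def test_recovers_truth_nuclei_with_noise(self, small_field):
        field, truth = small_field
        result = segment_nuclei(field.nuclear_channel, field.pixel_size_um)
        assert result.n_objects == truth.nucleus_truth_labels.n_objects

    def test_all_zero_image_errors(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((32, 32)), 0.1)

    def test_border_nucleus_kept(self):
        image = np.full((96, 96), 100.0)
        image[render_punctum((96, 96), (12.0, 48.0), 34.0)] = 4000.0  # ~26 µm² visible
        result = segment_nuclei(image, 0.1)
        assert result.n_objects == 1
        assert (result.labels[0, :] > 0).any()

    def test_debris_removed(self):
        image = np.full((96, 96), 100.0)
        image[render_punctum((96, 96), (48.0, 48.0), 26.0)] = 4000.0
        image[render_punctum((96, 96), (10.0, 10.0), 3.0)] = 4000.0  # 0.28 µm²
        result = segment_nuclei(image, 0.1, min_area_um2=20.0)
        assert result.n_objects == 1


# ------------------------------------------------------------------- cells

class TestSegmentCells:
    def test_two_separated_cells_contain_their_nuclei(self, noiseless_field):
        field, truth = noiseless_field
        nuclei = segment_nuclei(field.nuclear_channel, field.pixel_size_um)
        cells = segment_cells(field.cell_channel, nuclei, remove_border=False)
        assert cells.n_objects == truth.cell_truth_labels.n_objects
        for lab in range(1, nuclei.n_objects + 1):
            n_mask = nuclei.labels == lab
            owners = np.unique(cells.labels[n_mask])
            assert len(owners) == 1 and owners[0] > 0

    def test_identity_when_no_cytoplasm_stain(self, noiseless_field):
        field, _ = noiseless_field
        nuclei = segment_nuclei(field.nuclear_channel, field.pixel_size_um)
        cells = segment_cells(field.nuclear_channel, nuclei, remove_border=False)
        np.testing.assert_array_equal(cells.labels, nuclei.labels)

    def test_empty_nuclei_errors(self):
        with pytest.raises(ValueError, match="empty"):
            segment_cells(np.ones((16, 16)), LabelMap(np.zeros((16, 16), dtype=np.int32)))

    def test_blob_split_matches_brute_force_geodesic(self):
        """Two nuclei in one contiguous blob: the split must equal the
        per-pixel geodesic distance minimization exactly."""
        fg = np.zeros((24, 64), dtype=bool)
        fg[4:20, 2:62] = True
        fg[10:14, 30:34] = False  # hole making geodesic paths non-Euclidean
        seeds = np.zeros((24, 64), dtype=np.int32)
        seeds[10:14, 6:10] = 1
        seeds[10:14, 52:56] = 2
        got = propagate_labels(fg, seeds)
        want = geodesic_assign_brute(fg, seeds)
        np.testing.assert_array_equal(got, want)
        assert set(np.unique(got)) == {0, 1, 2}

    def test_tie_goes_to_lower_label(self):
        fg = np.ones((5, 11), dtype=bool)
        seeds = np.zeros((5, 11), dtype=np.int32)
        seeds[2, 1] = 1
        seeds[2, 9] = 2
        got = propagate_labels(fg, seeds)
        assert got[2, 5] == 1  # exactly equidistant centre column

    @pytest.mark.parametrize("seed", range(6))
    def test_propagation_matches_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        fg = rng.random((32, 32)) < 0.72
        seeds = np.zeros((32, 32), dtype=np.int32)
        placed = 0
        while placed < 3:
            r, c = rng.integers(0, 32, size=2)
            if seeds[r, c] == 0:
                placed += 1
                seeds[r, c] = placed
        got = propagate_labels(fg, seeds)
        want = geodesic_assign_brute(fg, seeds)
        np.testing.assert_array_equal(got, want)

    def test_border_cells_removed_and_relabeled(self):
        shape = (128, 128)
        nuclear = np.full(shape, 100.0)
        nuclear[render_punctum(shape, (64.0, 40.0), 26.0)] = 4000.0
        nuclear[render_punctum(shape, (24.0, 100.0), 28.0)] = 4000.0  # near border
        cellch = np.full(shape, 100.0)
        cellch[render_punctum(shape, (64.0, 40.0), 38.0)] = 700.0
        cellch[render_punctum(shape, (24.0, 100.0), 38.0)] = 700.0  # touches border
        nuclei = segment_nuclei(nuclear, 0.1)
        assert nuclei.n_objects == 2
        cells = segment_cells(cellch, nuclei, remove_border=True)
        assert cells.n_objects == 1
        assert not (
            (cells.labels[0, :] > 0).any() or (cells.labels[-1, :] > 0).any()
            or (cells.labels[:, 0] > 0).any() or (cells.labels[:, -1] > 0).any()
        )

    def test_structural_invariants_on_synthetic_field(self, small_field, small_result):
        """One nucleus per cell, nucleus nested in its cell, disjoint cells
        within the foreground union."""
        field, _ = small_field
        nuclei = small_result.nuclei
        cells = small_result.cells
        for cid in range(1, cells.n_objects + 1):
            inside = np.unique(nuclei.labels[cells.labels == cid])
            inside = inside[inside > 0]
            assert len(inside) == 1, f"cell {cid} contains {len(inside)} nuclei"
            n_mask = nuclei.labels == inside[0]
            covered = cells.labels[n_mask]
            assert np.all(covered == cid)  # nestedness
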