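"""Synthetic fluorescence-field generator with ground truth.

Emulates macrophage fields of view as imaged for mitochondrial morphology
scoring: each cell is a roughly circular body containing exactly one
nucleus and a mitochondrial compartment drawn as a mixture of small round
puncta (the *fragmented* phenotype — spherical, separated organelles) and
elongated curvilinear filaments (the *networked* phenotype — tubular,
fused organelles). Three channels are rendered — nuclear stain,
whole-cell stain, mitochondrial stain — then degraded by a Gaussian blur
(a proxy for the microscope PSF) and Poisson-Gaussian camera noise.

Every object is also recorded in noiseless truth label maps with its
class, so recovery of the fragmented fraction, per-cell counts and
lengths can be tested against known ground truth. Identical
(config, seed) pairs produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import LabelMap, MultiChannelField

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_field",
    "render_filament",
    "render_punctum",
]

#: Truth class names for mitochondrial objects.
FRAGMENTED = "fragmented"
NETWORKED = "networked"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic imaging condition.

    Defaults depict a resting-like macrophage field at 0.1 µm/pixel
    (high-magnification oil objective scale): cells ≈ 12 µm across, one
    ~6.4 µm nucleus each, ~15 mitochondrial objects per cell, half
    rendered as sub-µm² puncta and half as µm-scale filaments ~0.3 µm
    wide. Blur and noise levels are moderate so thresholding is stressed
    but not defeated.
    """

    field_shape: tuple[int, int] = (640, 640)
    pixel_size_um: float = 0.1
    n_cells: int = 10
    cell_radius_px: tuple[float, float] = (60.0, 4.0)  # mean, sd
    nucleus_radius_px: tuple[float, float] = (32.0, 2.0)  # mean, sd
    n_mito_per_cell: float = 15.0
    frag_fraction: float = 0.5
    punctum_radius_um: float = 0.4
    filament_length_um: float = 2.5
    filament_width_px: int = 3
    filament_curvature_max: float = 0.04  # |radians per pixel step|
    blur_sigma_px: float = 1.0
    noise_gain: float = 2.0  # photons per intensity unit scale; 0 disables
    noise_read_sd: float = 8.0  # additive Gaussian read noise; 0 disables
    bg_level: float = 100.0
    cyto_level: float = 600.0
    nucleus_level: float = 4000.0
    mito_level: float = 4000.0
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_shape
        if h <= 0 or w <= 0:
            raise ValueError(f"field_shape must be positive, got {self.field_shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.frag_fraction <= 1.0):
            raise ValueError(f"frag_fraction must lie in [0,1], got {self.frag_fraction}")
        for name in ("punctum_radius_um", "filament_length_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("cell_radius_px", "nucleus_radius_px"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} mean must be > 0 and sd >= 0")
        if self.filament_width_px < 1:
            raise ValueError("filament_width_px must be >= 1")
        if self.n_mito_per_cell < 0:
            raise ValueError("n_mito_per_cell must be >= 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_shape"] = list(d["field_shape"])
        d["cell_radius_px"] = list(d["cell_radius_px"])
        d["nucleus_radius_px"] = list(d["nucleus_radius_px"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("field_shape", "cell_radius_px", "nucleus_radius_px"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth of one field, before blur and noise."""

    cell_truth_labels: LabelMap
    nucleus_truth_labels: LabelMap
    mito_truth_labels: LabelMap
    per_object_class: dict[int, str] = field(default_factory=dict)
    per_cell_counts: dict[int, tuple[int, int]] = field(default_factory=dict)
    per_cell_mean_length_um: dict[int, float] = field(default_factory=dict)
    object_cell: dict[int, int] = field(default_factory=dict)
    object_length_um: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.mito_truth_labels.n_objects
        if set(self.per_object_class) != set(range(1, n + 1)):
            raise ValueError("every mito truth label needs exactly one class entry")
        total = sum(nf + nn for nf, nn in self.per_cell_counts.values())
        if total != n:
            raise ValueError("per-cell counts do not sum to the truth object count")

    @property
    def n_objects(self) -> int:
        return self.mito_truth_labels.n_objects

    @property
    def fragmented_fraction(self) -> float:
        if self.n_objects == 0:
            return float("nan")
        frag = sum(1 for c in self.per_object_class.values() if c == FRAGMENTED)
        return frag / self.n_objects


# --------------------------------------------------------------- primitives

def render_punctum(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Anti-aliased disk binarized at 0.5: pixel centers within the radius.

    Keeps the truth area analytic (πr²) within a one-pixel boundary band.
    """
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    mask = np.zeros(shape, dtype=bool)
    r0 = max(int(center[0] - radius_px) - 1, 0)
    r1 = min(int(center[0] + radius_px) + 2, shape[0])
    c0 = max(int(center[1] - radius_px) - 1, 0)
    c1 = min(int(center[1] + radius_px) + 2, shape[1])
    if r1 <= r0 or c1 <= c0:
        return mask
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    dist = np.hypot(rows - center[0], cols - center[1])
    coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    mask[r0:r1, c0:c1] = coverage >= 0.5
    return mask


def filament_path(
    start: tuple[float, float],
    length_um: float,
    curvature: float,
    pixel_size_um: float,
    heading: float = 0.0,
) -> np.ndarray:
    """Subpixel centre-line of a constant-curvature stroke, one point per
    1-px arc step; returned as an (n, 2) float array of (row, col)."""
    if not (length_um > 0):
        raise ValueError(f"filament length must be > 0, got {length_um}")
    n_steps = int(round(length_um / pixel_size_um))
    pts = np.empty((n_steps + 1, 2))
    r, c = float(start[0]), float(start[1])
    theta = float(heading)
    pts[0] = (r, c)
    for i in range(n_steps):
        r += math.sin(theta)
        c += math.cos(theta)
        theta += curvature
        pts[i + 1] = (r, c)
    return pts


def render_filament(
    start: tuple[float, float],
    length_um: float,
    width_px: int,
    curvature: float,
    pixel_size_um: float,
    shape: tuple[int, int],
    heading: float = 0.0,
) -> np.ndarray:
    """Rasterize one curvilinear filament of given end-to-end arc length.

    The stroke is an 8-connected unit-step walk of constant curvature
    (radians per pixel step) thickened to ``width_px`` by dilation, so its
    geodesic path length tracks ``length_um / pixel_size_um`` pixels. A
    stroke whose aspect ratio (length/width) is below 2 would be
    punctum-like and is rejected.
    """
    if not (length_um > 0):
        raise ValueError(f"filament length must be > 0, got {length_um}")
    length_px = length_um / pixel_size_um
    if length_px < 2 * width_px:
        raise ValueError(
            f"degenerate filament: length {length_px:.1f} px vs width {width_px} px "
            "(aspect < 2 is punctum-like; render a punctum instead)"
        )
    pts = filament_path(start, length_um, curvature, pixel_size_um, heading)
    mask = np.zeros(shape, dtype=bool)
    rr = np.rint(pts[:, 0]).astype(int)
    cc = np.rint(pts[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    mask[rr[keep], cc[keep]] = True
    if not mask.any():
        raise ValueError("filament lies entirely outside the field")
    radius = (width_px - 1) // 2
    if radius > 0:
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        selem = (yy ** 2 + xx ** 2) <= radius ** 2 + 0.5
        _dilate_in_place(mask, selem)
    return mask


def _dilate_in_place(mask: np.ndarray, selem: np.ndarray) -> None:
    """Binary dilation restricted to the mask's padded bounding box."""
    rr, cc = np.nonzero(mask)
    pad = max(selem.shape) // 2 + 1
    r0 = max(int(rr.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, mask.shape[0])
    c0 = max(int(cc.min()) - pad, 0)
    c1 = min(int(cc.max()) + pad + 1, mask.shape[1])
    mask[r0:r1, c0:c1] = ndimage.binary_dilation(mask[r0:r1, c0:c1], structure=selem)


# --------------------------------------------------------------- placement

def _sample_radius(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw clipped to mean ± 2 sd (keeps geometry sane)."""
    return float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd))


def _place_cells(
    rng: np.random.Generator, config: GeneratorConfig
) -> list[tuple[float, float, float, float]]:
    """(row, col, cell_radius, nucleus_radius) per cell; cell disks are kept
    disjoint, fully inside the field, with a small inter-cell gap."""
    h, w = config.field_shape
    placed: list[tuple[float, float, float, float]] = []
    gap = 3.0
    for i in range(config.n_cells):
        cell_r = _sample_radius(rng, *config.cell_radius_px)
        nuc_r = min(
            _sample_radius(rng, *config.nucleus_radius_px), 0.7 * cell_r
        )
        for attempt in range(config.max_retries):
            r = rng.uniform(cell_r + 1, h - cell_r - 1) if h > 2 * (cell_r + 1) else None
            c = rng.uniform(cell_r + 1, w - cell_r - 1) if w > 2 * (cell_r + 1) else None
            if r is None or c is None:
                break
            if all(
                math.hypot(r - pr, c - pc) >= cell_r + p_cr + gap
                for pr, pc, p_cr, _ in placed
            ):
                placed.append((r, c, cell_r, nuc_r))
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{config.n_cells} after "
                f"{config.max_retries} retries: {config.n_cells} cells of radius "
                f"~{config.cell_radius_px[0]:.0f} px are too dense for a "
                f"{h}x{w} field"
            )
        if len(placed) != i + 1:
            raise RuntimeError(
                f"field too small for a cell of radius {cell_r:.0f} px "
                f"({h}x{w} pixels)"
            )
    return placed


# --------------------------------------------------------------- generator

def generate_field(
    config: GeneratorConfig, field_id: str = "synthetic_0"
) -> tuple[MultiChannelField, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Cells are placed by rejection sampling (failing loudly when the
    requested density cannot fit). Each cell receives round(n_mito_per_cell)
    mitochondrial objects; each object is independently a punctum with
    probability ``frag_fraction``, otherwise a filament. Objects are kept
    inside their cell's cytoplasm and mutually separated by ≥3 px so truth
    components never merge. Truth maps are recorded before blur and noise.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.field_shape
    px = config.pixel_size_um

    cell_lab = np.zeros(shape, dtype=np.int32)
    nuc_lab = np.zeros(shape, dtype=np.int32)
    mito_lab = np.zeros(shape, dtype=np.int32)
    per_object_class: dict[int, str] = {}
    object_cell: dict[int, int] = {}
    object_length: dict[int, float] = {}

    cells = _place_cells(rng, config)
    for cid, (r, c, cell_r, nuc_r) in enumerate(cells, start=1):
        cell_mask = render_punctum(shape, (r, c), cell_r)
        nuc_mask = render_punctum(shape, (r, c), nuc_r)
        cell_lab[cell_mask] = cid
        nuc_lab[nuc_mask] = cid

    sep = np.zeros(shape, dtype=bool)  # occupied zone: objects + 3 px margin
    sep_selem = np.ones((7, 7), dtype=bool)
    next_obj = 1
    n_per_cell = int(round(config.n_mito_per_cell))
    punctum_r_px = config.punctum_radius_um / px
    min_fil_len_um = 5 * config.filament_width_px * px

    for cid, (r, c, cell_r, nuc_r) in enumerate(cells, start=1):
        for _ in range(n_per_cell):
            as_punctum = rng.random() < config.frag_fraction
            mask = None
            for _attempt in range(200):
                if as_punctum:
                    rad = float(
                        np.clip(
                            rng.normal(punctum_r_px, 0.1 * punctum_r_px),
                            0.75 * punctum_r_px,
                            1.25 * punctum_r_px,
                        )
                    )
                    lo = nuc_r + rad + 2
                    hi = cell_r - rad - 2
                    if hi <= lo:
                        break
                    rho = rng.uniform(lo, hi)
                    phi = rng.uniform(0, 2 * math.pi)
                    cand = render_punctum(
                        shape, (r + rho * math.sin(phi), c + rho * math.cos(phi)), rad
                    )
                    length_um = 0.0
                else:
                    length = max(
                        rng.normal(config.filament_length_um, 0.15 * config.filament_length_um),
                        min_fil_len_um,
                    )
                    half_w = (config.filament_width_px + 1) / 2
                    lo = nuc_r + half_w + 2
                    hi = cell_r - half_w - 2
                    if hi <= lo:
                        break
                    rho = rng.uniform(lo, hi)
                    phi = rng.uniform(0, 2 * math.pi)
                    start = (r + rho * math.sin(phi), c + rho * math.cos(phi))
                    heading = rng.uniform(0, 2 * math.pi)
                    curv = rng.uniform(
                        -config.filament_curvature_max, config.filament_curvature_max
                    )
                    pts = filament_path(start, length, curv, px, heading)
                    d_centre = np.hypot(pts[:, 0] - r, pts[:, 1] - c)
                    if (d_centre < nuc_r + half_w + 1).any() or (
                        d_centre > cell_r - half_w - 1
                    ).any():
                        continue
                    cand = render_filament(
                        start, length, config.filament_width_px, curv, px, shape, heading
                    )
                    length_um = length
                if (cand & sep).any():
                    continue
                mask = cand
                break
            if mask is None:
                continue  # crowded cell: drop this object, truth stays consistent
            mito_lab[mask] = next_obj
            margin = mask.copy()
            _dilate_in_place(margin, sep_selem)
            sep |= margin
            per_object_class[next_obj] = FRAGMENTED if as_punctum else NETWORKED
            object_cell[next_obj] = cid
            object_length[next_obj] = length_um
            next_obj += 1

    per_cell_counts: dict[int, tuple[int, int]] = {}
    per_cell_len: dict[int, float] = {}
    for cid in range(1, len(cells) + 1):
        mine = [oid for oid, oc in object_cell.items() if oc == cid]
        nf = sum(1 for oid in mine if per_object_class[oid] == FRAGMENTED)
        per_cell_counts[cid] = (nf, len(mine) - nf)
        per_cell_len[cid] = (
            float(np.mean([object_length[oid] for oid in mine])) if mine else float("nan")
        )

    # --- intensity rendering -------------------------------------------
    nuclear = np.full(shape, config.bg_level, dtype=np.float64)
    cellch = np.full(shape, config.bg_level, dtype=np.float64)
    mitoch = np.full(shape, config.bg_level, dtype=np.float64)
    nuclear[nuc_lab > 0] += config.nucleus_level
    cellch[cell_lab > 0] += config.cyto_level
    cellch[nuc_lab > 0] += 0.5 * config.cyto_level  # stain accumulates over nuclei
    mitoch[mito_lab > 0] += config.mito_level

    if config.blur_sigma_px > 0:
        for img in (nuclear, cellch, mitoch):
            img[...] = ndimage.gaussian_filter(img, config.blur_sigma_px)
    if config.noise_gain > 0:
        for img in (nuclear, cellch, mitoch):
            img[...] = rng.poisson(img / config.noise_gain) * config.noise_gain
    if config.noise_read_sd > 0:
        for img in (nuclear, cellch, mitoch):
            img[...] = img + rng.normal(0.0, config.noise_read_sd, size=shape)
    for img in (nuclear, cellch, mitoch):
        np.clip(img, 0.0, None, out=img)

    fieldobj = MultiChannelField(
        nuclear_channel=nuclear,
        cell_channel=cellch,
        mito_channel=mitoch,
        pixel_size_um=px,
        field_id=field_id,
    )
    truth = GroundTruth(
        cell_truth_labels=LabelMap(cell_lab),
        nucleus_truth_labels=LabelMap(nuc_lab),
        mito_truth_labels=LabelMap(mito_lab),
        per_object_class=per_object_class,
        per_cell_counts=per_cell_counts,
        per_cell_mean_length_um=per_cell_len,
        object_cell=object_cell,
        object_length_um=object_length,
    )
    return fieldobj, truth
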