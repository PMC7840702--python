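"""Core data containers for calibrated multichannel fields and label maps.

A *field* is one imaged position: three co-registered 2D intensity arrays
(nuclear stain, whole-cell stain, mitochondrial stain) plus the pixel size
in micrometres per pixel. A :class:`LabelMap` is an integer mask over the
same geometry, 0 = background, labels consecutive from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MultiChannelField", "LabelMap", "CHANNEL_ROLES"]

#: Canonical channel roles, in storage order for multipage TIFFs.
CHANNEL_ROLES = ("nuclear", "cell", "mito")


@dataclass(frozen=True)
class MultiChannelField:
    """Calibrated three-channel field of view.

    Parameters
    ----------
    nuclear_channel, cell_channel, mito_channel
        2D non-negative intensity arrays of identical shape. The nuclear
        channel plays the DAPI role, the cell channel the whole-cell
        (CellTracker-type) role, and the mito channel the mitochondrial
        marker (Complex I-type) role.
    pixel_size_um
        Lateral calibration in µm/pixel, strictly positive.
    field_id
        Opaque identifier used in output tables.
    """

    nuclear_channel: np.ndarray
    cell_channel: np.ndarray
    mito_channel: np.ndarray
    pixel_size_um: float
    field_id: str = "field_0"

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(self.nuclear_channel).shape,
            np.asarray(self.cell_channel).shape,
            np.asarray(self.mito_channel).shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for name in ("nuclear_channel", "cell_channel", "mito_channel"):
            arr = getattr(self, name)
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{name} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear_channel.shape

    def channel(self, role: str) -> np.ndarray:
        if role not in CHANNEL_ROLES:
            raise KeyError(f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
        return getattr(self, f"{role}_channel")

    # ------------------------------------------------------------------ IO
    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write one 16-bit single-page TIFF per channel; return the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for role in CHANNEL_ROLES:
            arr = np.clip(np.rint(self.channel(role)), 0, 65535).astype(np.uint16)
            path = directory / f"{self.field_id}_{role}.tif"
            tifffile.imwrite(path, arr)
            paths[role] = path
        return paths

    @classmethod
    def load(
        cls,
        nuclear: str | Path,
        cell: str | Path,
        mito: str | Path,
        pixel_size_um: float,
        field_id: str | None = None,
    ) -> "MultiChannelField":
        """Read a field from three per-channel TIFF files."""
        arrays = {}
        for role, path in zip(CHANNEL_ROLES, (nuclear, cell, mito)):
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"missing {role} channel file: {path}")
            try:
                arrays[role] = np.asarray(tifffile.imread(path)).astype(np.float64)
            except Exception as exc:  # pragma: no cover - tifffile error text varies
                raise ValueError(f"unreadable TIFF for {role} channel: {path}") from exc
        if field_id is None:
            field_id = Path(nuclear).stem.replace("_nuclear", "")
        return cls(
            nuclear_channel=arrays["nuclear"],
            cell_channel=arrays["cell"],
            mito_channel=arrays["mito"],
            pixel_size_um=pixel_size_um,
            field_id=field_id,
        )

    @classmethod
    def load_multipage(
        cls,
        path: str | Path,
        pixel_size_um: float,
        channel_order: tuple[str, str, str] = CHANNEL_ROLES,
        field_id: str | None = None,
    ) -> "MultiChannelField":
        """Read a field from one multipage TIFF with a declared channel order."""
        stack = np.asarray(tifffile.imread(path))
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(
                f"multipage field must have 3 pages, got shape {stack.shape} in {path}"
            )
        if sorted(channel_order) != sorted(CHANNEL_ROLES):
            raise ValueError(f"channel_order must be a permutation of {CHANNEL_ROLES}")
        by_role = {role: stack[i].astype(np.float64) for i, role in enumerate(channel_order)}
        return cls(
            nuclear_channel=by_role["nuclear"],
            cell_channel=by_role["cell"],
            mito_channel=by_role["mito"],
            pixel_size_um=pixel_size_um,
            field_id=field_id or Path(path).stem,
        )


@dataclass(frozen=True)
class LabelMap:
    """Integer-labeled segmentation mask; labels are consecutive 1..n_objects.

    Connectivity of each object's pixel set is 8-connected throughout the
    pipeline.
    """

    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label map must be 2D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"label map must be integer-typed, got {labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ValueError("label map contains negative labels")
        present = np.unique(labels)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if present.size != n:
            raise ValueError("labels must be consecutive 1..n with no gaps")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def save(self, path: str | Path) -> Path:
        """Write as a 16-bit TIFF label mask."""
        path = Path(path)
        if self.n_objects > 65535:
            raise ValueError("too many labels for a 16-bit mask")
        tifffile.imwrite(path, self.labels.astype(np.uint16))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        return cls(np.asarray(tifffile.imread(path)).astype(np.int32))


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary positive labels to consecutive 1..n, preserving order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]
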