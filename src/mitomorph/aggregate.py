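"""Relating mitochondrial objects to cells and summary statistics.

Child objects (mitochondria) are assigned to parent objects (cells) by
majority pixel overlap; per-cell records are then rolled up first within
each independent experiment (cells are the replicates inside an
experiment) and then across experiments (experiments, not cells, are the
unit of averaging, so experiments with different cell counts weigh
equally in the reported condition mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import LabelMap
from .objects import MitoObject
from .skeletons import SkeletonMeasure

__all__ = [
    "PerCellMorphology",
    "ConditionSummary",
    "relate_objects",
    "summarize_cells",
    "summarize_condition",
    "per_cell_frame",
]


@dataclass(frozen=True)
class PerCellMorphology:
    """Single-cell morphology record.

    ``fragmented_fraction`` and ``mean_mito_length_um`` are NaN (missing),
    never zero, for cells without mitochondrial objects.
    """

    field_id: str
    cell_id: int
    n_mito: int
    n_fragmented: int
    n_nonfragmented: int
    fragmented_fraction: float
    total_mito_area_um2: float
    mean_mito_length_um: float
    cell_area_um2: float

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be positive")
        if self.n_fragmented + self.n_nonfragmented != self.n_mito:
            raise ValueError("fragmented + non-fragmented must equal n_mito")
        if self.n_mito > 0:
            expected = self.n_fragmented / self.n_mito
            if not math.isclose(self.fragmented_fraction, expected):
                raise ValueError("fragmented_fraction inconsistent with counts")
        elif not math.isnan(self.fragmented_fraction):
            raise ValueError("fragmented_fraction must be missing for 0 objects")


@dataclass(frozen=True)
class ConditionSummary:
    """Cell-averaged readouts of one condition in one experiment."""

    condition: str
    experiment_id: str
    n_cells: int
    mean_fragmented_per_cell: float
    mean_length_um: float

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("a summary requires at least one cell")


def relate_objects(
    mito_labels: LabelMap, cell_labels: LabelMap
) -> dict[int, int | None]:
    """Assign each mitochondrial object to the cell covering most of its
    pixels.

    If background covers strictly more pixels than any single cell the
    object is unassigned (None) — e.g. an object whose parent cell was
    removed as border-touching. Exact ties between two cells go to the
    lower cell label; a tie between a cell and background goes to the cell.
    """
    if mito_labels.shape != cell_labels.shape:
        raise ValueError(
            f"label map shapes differ: {mito_labels.shape} vs {cell_labels.shape}"
        )
    mito = mito_labels.labels
    cells = cell_labels.labels
    n_cells = cell_labels.n_objects
    out: dict[int, int | None] = {}
    inside = mito > 0
    # joint histogram of (object, parent) over mito-foreground pixels
    pair = mito[inside].astype(np.int64) * (n_cells + 1) + cells[inside].astype(np.int64)
    counts = np.bincount(pair, minlength=(mito_labels.n_objects + 1) * (n_cells + 1))
    counts = counts.reshape(mito_labels.n_objects + 1, n_cells + 1)
    for oid in range(1, mito_labels.n_objects + 1):
        row = counts[oid]
        if n_cells == 0:
            out[oid] = None
            continue
        best_cell = int(np.argmax(row[1:])) + 1  # argmax returns lowest index on ties
        if row[0] > row[best_cell]:
            out[oid] = None
        else:
            out[oid] = best_cell
    return out


def summarize_cells(
    objects: list[MitoObject],
    lengths: list[SkeletonMeasure],
    cells: LabelMap,
    pixel_size_um: float,
    field_id: str = "field_0",
) -> list[PerCellMorphology]:
    """One record per surviving cell, including cells with zero mitochondria.

    Conservation holds by construction: the per-cell ``n_mito`` sum equals
    the number of objects with a non-None ``cell_id``.
    """
    length_by_id = {m.object_id: m.length_um for m in lengths}
    missing = [o.object_id for o in objects if o.object_id not in length_by_id]
    if missing:
        raise KeyError(f"objects without skeleton measures: {sorted(missing)}")
    seen: set[int] = set()
    for o in objects:
        if o.object_id in seen:
            raise ValueError(f"duplicate object_id {o.object_id}")
        seen.add(o.object_id)
        if o.cell_id is not None and not (1 <= o.cell_id <= cells.n_objects):
            raise ValueError(f"object {o.object_id} refers to unknown cell {o.cell_id}")

    px_area = pixel_size_um ** 2
    cell_areas = np.bincount(cells.labels.ravel(), minlength=cells.n_objects + 1)
    rows: list[PerCellMorphology] = []
    for cid in range(1, cells.n_objects + 1):
        mine = [o for o in objects if o.cell_id == cid]
        n_mito = len(mine)
        n_frag = sum(o.is_fragmented for o in mine)
        frag_fraction = n_frag / n_mito if n_mito else float("nan")
        mean_len = (
            float(np.mean([length_by_id[o.object_id] for o in mine]))
            if n_mito
            else float("nan")
        )
        rows.append(
            PerCellMorphology(
                field_id=field_id,
                cell_id=cid,
                n_mito=n_mito,
                n_fragmented=n_frag,
                n_nonfragmented=n_mito - n_frag,
                fragmented_fraction=frag_fraction,
                total_mito_area_um2=float(sum(o.area_um2 for o in mine)),
                mean_mito_length_um=mean_len,
                cell_area_um2=float(cell_areas[cid]) * px_area,
            )
        )
    return rows


def per_cell_frame(rows: list[PerCellMorphology]) -> pd.DataFrame:
    """Per-cell records as a tidy DataFrame (one row per cell)."""
    return pd.DataFrame([vars(r) for r in rows])


def _stable_mean(values: pd.Series) -> float:
    """Mean over non-missing values, summed in sorted order so the result
    is bit-identical under any permutation of the input rows."""
    arr = np.sort(np.asarray(values, dtype=np.float64))
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def summarize_condition(
    per_cell: pd.DataFrame,
    condition_col: str = "condition",
    experiment_col: str = "experiment_id",
) -> tuple[list[ConditionSummary], pd.DataFrame]:
    """Two-stage averaging: cells within an experiment, then experiments.

    ``per_cell`` needs columns ``condition``, ``experiment_id``,
    ``n_fragmented`` and ``mean_mito_length_um`` (NaN rows for cells with
    no mitochondria are ignored by the length mean, as missing values,
    never treated as zero). Returns the per-experiment summaries and a
    grand-mean table per condition with the across-experiment sample SD
    (NaN for a single experiment).
    """
    required = {condition_col, experiment_col, "n_fragmented", "mean_mito_length_um"}
    missing = required - set(per_cell.columns)
    if missing:
        raise KeyError(f"per-cell table lacks columns: {sorted(missing)}")
    if per_cell.empty:
        raise ValueError("no cells to summarize (empty per-cell table)")

    summaries: list[ConditionSummary] = []
    for (cond, exp), group in sorted(
        per_cell.groupby([condition_col, experiment_col], sort=False),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
    ):
        if len(group) == 0:  # defensive: groupby never yields empty groups
            raise ValueError(f"experiment {exp!r} of condition {cond!r} has zero cells")
        summaries.append(
            ConditionSummary(
                condition=str(cond),
                experiment_id=str(exp),
                n_cells=int(len(group)),
                mean_fragmented_per_cell=_stable_mean(group["n_fragmented"]),
                mean_length_um=_stable_mean(group["mean_mito_length_um"]),
            )
        )
    per_exp = pd.DataFrame([vars(s) for s in summaries])
    grand = (
        per_exp.groupby("condition", sort=True)
        .agg(
            n_experiments=("experiment_id", "nunique"),
            mean_fragmented_per_cell=("mean_fragmented_per_cell", "mean"),
            sd_fragmented_per_cell=("mean_fragmented_per_cell", lambda s: s.std(ddof=1)),
            mean_length_um=("mean_length_um", "mean"),
            sd_length_um=("mean_length_um", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    return summaries, grand
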