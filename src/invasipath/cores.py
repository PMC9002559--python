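"""Core habitat areas: connected suitable patches above an area threshold.

A core is a maximal connected region (8-connectivity by default) of the
binary suitability map with area of at least 1 km² — large enough to act as
a colonization source.  Cores intersecting a presence record are flagged as
confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import RasterLayer

__all__ = ["CorePatch", "label_patches", "filter_cores", "confirm_cores",
           "extract_cores"]


@dataclass
class CorePatch:
    id: int
    cells: np.ndarray            # (n, 2) row/col indices
    area_km2: float
    centroid: tuple[float, float]
    confirmed: bool = False


_STRUCT = {
    8: np.ones((3, 3), dtype=int),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
}


def label_patches(
    binary: RasterLayer, connectivity: int = 8
) -> tuple[RasterLayer, list[np.ndarray]]:
    """Label maximal connected sets of 1-cells.

    Labels are canonicalized in row-major order of each patch's first cell,
    so output is invariant to how the underlying labeling visits the grid.
    Returns the labeled raster (0 = background) and each patch's cell array.
    """
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    vals = binary.values
    ones = np.nan_to_num(vals, nan=0.0) == 1.0
    raw, n = ndimage.label(ones, structure=_STRUCT[connectivity])
    # canonical order: first cell (row-major) of each raw label
    order = []
    flat = raw.ravel()
    first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.arange(flat.size)
    np.minimum.at(first, flat, idx)
    order = np.argsort(first[1:], kind="stable")  # raw label k+1 -> rank
    remap = np.zeros(n + 1, dtype=int)
    remap[order + 1] = np.arange(1, n + 1)
    lab = remap[raw]
    patches = [
        np.column_stack(np.nonzero(lab == k)) for k in range(1, n + 1)
    ]
    out = binary.copy_with(lab.astype(float), kind="categorical", name="cores")
    out.values[np.isnan(vals)] = np.nan
    return out, patches


def filter_cores(
    patches: list[np.ndarray],
    min_area_km2: float = 1.0,
    cell_size_m: float = 100.0,
    grid: RasterLayer | None = None,
) -> list[CorePatch]:
    """Keep patches with area >= min_area_km2 (strictly smaller removed).

    At 100 m cells one cell is 0.01 km², so the default keeps patches of
    100 cells and removes 99-cell ones.
    """
    if min_area_km2 < 0:
        raise ValueError("min_area_km2 must be nonnegative")
    cell_km2 = (cell_size_m / 1000.0) ** 2
    out: list[CorePatch] = []
    next_id = 1
    for cells in patches:
        area = len(cells) * cell_km2
        if area < min_area_km2:
            continue
        if grid is not None:
            xy = np.array(
                [grid.cell_center(int(r), int(c)) for r, c in cells]
            )
            centroid = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        else:
            centroid = (
                float(cells[:, 1].mean() * cell_size_m),
                float(cells[:, 0].mean() * cell_size_m),
            )
        out.append(
            CorePatch(
                id=next_id, cells=cells, area_km2=area, centroid=centroid
            )
        )
        next_id += 1
    return out


def confirm_cores(
    cores: list[CorePatch],
    occurrences: OccurrenceSet,
    grid: RasterLayer,
) -> list[CorePatch]:
    """Flag cores containing at least one occurrence point (point-in-patch)."""
    occ_cells = {
        (int(r), int(c)) for r, c in occurrences.cells(grid)
    } if len(occurrences) else set()
    for core in cores:
        core.confirmed = any(
            (int(r), int(c)) in occ_cells for r, c in core.cells
        )
    return cores


def extract_cores(
    binary: RasterLayer,
    occurrences: OccurrenceSet | None = None,
    min_area_km2: float = 1.0,
    connectivity: int = 8,
) -> tuple[RasterLayer, list[CorePatch]]:
    """Label, filter and (optionally) confirm cores in one call.

    The returned raster labels only the surviving cores, by their final ids.
    """
    _, patches = label_patches(binary, connectivity=connectivity)
    cores = filter_cores(
        patches, min_area_km2, binary.cell_size, grid=binary
    )
    if occurrences is not None:
        confirm_cores(cores, occurrences, binary)
    lab = np.zeros(binary.shape)
    for core in cores:
        lab[core.cells[:, 0], core.cells[:, 1]] = core.id
    lab[np.isnan(binary.values)] = np.nan
    return binary.copy_with(lab, kind="categorical", name="cores"), cores


def cores_table(cores: list[CorePatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "n_cells": len(c.cells),
                "area_km2": c.area_km2,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "confirmed": c.confirmed,
            }
            for c in cores
        ]
    )
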