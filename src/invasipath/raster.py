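"""Grid container and text raster I/O.

A :class:`RasterLayer` is the universal carrier for every gridded quantity in
the pipeline: predictors, suitability probabilities, binary habitat maps,
resistance surfaces, catchment partitions.  Grids are north-up (row 0 is the
northern edge), square-celled, on a single projected CRS in meters.  World
coordinates refer to cell centers.  Nodata is carried as NaN internally.

Rasters serialize to the ESRI ASCII grid format (``.asc``), a plain-text
header (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by
row-major values — readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterLayer", "read_ascii_grid", "write_ascii_grid"]

_ASCII_NODATA = -9999.0


@dataclass
class RasterLayer:
    """A georeferenced 2D grid.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values, float; NaN marks nodata.  Categorical layers store
        integer class codes as floats.
    cell_size : float
        Square cell edge length in meters.
    origin : (float, float)
        ``(x, y)`` of the grid's lower-left *corner* in world coordinates.
    kind : {"continuous", "categorical"}
        Interpolation/encoding behavior downstream.
    name : str
        Layer name (field-standard abbreviation for predictors).
    """

    values: np.ndarray
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    kind: str = "continuous"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterLayer values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of a cell center (north-up convention)."""
        nrows = self.values.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid index containing a world point; raises if off-grid."""
        nrows, ncols = self.values.shape
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(nrows - 1 - np.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def same_grid(self, other: "RasterLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, values: np.ndarray, **kw) -> "RasterLayer":
        """New layer on the same grid with different values."""
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    # -- I/O --------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        write_ascii_grid(self, path)


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (text)."""
    path = Path(path)
    vals = np.where(np.isnan(layer.values), _ASCII_NODATA, layer.values)
    nrows, ncols = layer.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {layer.origin[0]:.6f}\n")
        fh.write(f"yllcorner {layer.origin[1]:.6f}\n")
        fh.write(f"cellsize {layer.cell_size:.6f}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA:g}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(
    path: str | Path, kind: str = "continuous", name: str = ""
) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _ASCII_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: header/data shape mismatch")
    return RasterLayer(
        values=vals,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        kind=kind,
        name=name or path.stem,
    )
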