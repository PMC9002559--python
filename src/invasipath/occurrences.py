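"""Presence point records.

Occurrences are point tables ``(x, y, source)`` in world meters.  Points are
validated against the predictor grid before training: every point must land
on a non-nodata cell; multiple points in one cell are deduplicated for model
fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterLayer

__all__ = ["OccurrenceSet"]


@dataclass
class OccurrenceSet:
    points: list[tuple[float, float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["x", "y", "source"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        pts = [
            (float(r.x), float(r.y), str(r.source))
            for r in df.itertuples(index=False)
        ]
        return cls(pts)

    def cells(self, grid: RasterLayer, dedupe: bool = False) -> np.ndarray:
        """(row, col) indices of each point; validates on-grid, non-nodata.

        Raises ValueError listing offending rows.
        """
        out, bad = [], []
        for k, (x, y, _src) in enumerate(self.points):
            try:
                r, c = grid.index_of(x, y)
            except ValueError:
                bad.append(k)
                continue
            if np.isnan(grid.values[r, c]):
                bad.append(k)
                continue
            out.append((r, c))
        if bad:
            raise ValueError(
                f"occurrence rows fall off-grid or on nodata cells: {bad}"
            )
        arr = np.asarray(out, dtype=int).reshape(-1, 2)
        if dedupe and len(arr):
            arr = np.unique(arr, axis=0)
        return arr

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls.from_frame(pd.read_csv(path))

    def write_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"source": src},
            }
            for x, y, src in self.points
        ]
        with open(path, "w") as fh:
            json.dump(
                {"type": "FeatureCollection", "features": features}, fh
            )
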