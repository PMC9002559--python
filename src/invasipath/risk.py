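"""Invasion-risk classification of corridors by catchment crossing.

A riparian invader spreads readily within one river catchment (water carries
the seed), but jumping between catchments needs human assistance.  A
corridor confined to a single catchment is therefore high risk; one crossing
two to five catchments is medium; six or more, low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import Corridor
from .raster import RasterLayer

__all__ = [
    "RiskSummary",
    "count_catchments",
    "classify_risk",
    "classify_corridors",
    "summarize",
]

RISK_CLASSES = ("high", "medium", "low")


def count_catchments(corridor: Corridor, catchments: RasterLayer) -> int:
    """Distinct catchment ids under the corridor's LCP cell trace."""
    if not corridor.lcp_cells:
        raise ValueError("corridor has no LCP cells")
    vals = [
        catchments.values[r, c]
        for r, c in corridor.lcp_cells
    ]
    ids = {int(v) for v in vals if not np.isnan(v)}
    if not ids:
        raise ValueError("corridor lies entirely on nodata catchment cells")
    corridor.catchment_ids = ids
    return len(ids)


def classify_risk(n_catchments: int) -> str:
    """high (1 catchment), medium (2-5), low (6 or more)."""
    if n_catchments < 1:
        raise ValueError("a corridor intersects at least one catchment")
    if n_catchments == 1:
        return "high"
    if n_catchments <= 5:
        return "medium"
    return "low"


def classify_corridors(
    corridors: list[Corridor], catchments: RasterLayer
) -> list[Corridor]:
    """Count catchments and attach a risk class to each corridor."""
    for cor in corridors:
        cor.risk = classify_risk(count_catchments(cor, catchments))
    return corridors


@dataclass
class ClassStats:
    count: int = 0
    total_km: float = 0.0
    mean_km: float = float("nan")
    max_km: float = float("nan")
    min_km: float = float("nan")
    confirmed_count: int = 0


@dataclass
class RiskSummary:
    per_class: dict[str, ClassStats] = field(default_factory=dict)

    @property
    def total_corridors(self) -> int:
        return sum(s.count for s in self.per_class.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in RISK_CLASSES:
            s = self.per_class.get(cls, ClassStats())
            rows.append(
                {
                    "risk": cls,
                    "count": s.count,
                    "total_km": s.total_km,
                    "mean_km": s.mean_km,
                    "mean_km_rounded": (
                        int(round(s.mean_km)) if s.count else 0
                    ),
                    "max_km": s.max_km,
                    "min_km": s.min_km,
                    "confirmed_count": s.confirmed_count,
                }
            )
        return pd.DataFrame(rows)


def summarize(corridors: list[Corridor]) -> RiskSummary:
    """Per-class corridor count and length statistics.

    Means are reported raw; the tabular output adds a nearest-integer
    rounding column for presentation.
    """
    out = RiskSummary()
    for cls in RISK_CLASSES:
        lengths = np.array(
            [c.length_km for c in corridors if c.risk == cls]
        )
        n_conf = sum(
            1 for c in corridors if c.risk == cls and c.touches_confirmed
        )
        if lengths.size:
            out.per_class[cls] = ClassStats(
                count=int(lengths.size),
                total_km=float(lengths.sum()),
                mean_km=float(lengths.sum() / lengths.size),
                max_km=float(lengths.max()),
                min_km=float(lengths.min()),
                confirmed_count=n_conf,
            )
        else:
            out.per_class[cls] = ClassStats()
    unknown = [c for c in corridors if c.risk not in RISK_CLASSES]
    if unknown:
        raise ValueError(f"{len(unknown)} corridors lack a risk class")
    return out


def risk_raster(
    corridors: list[Corridor], grid: RasterLayer
) -> RasterLayer:
    """Rasterize classified corridors: high=3, medium=2, low=1, else 0.

    Where corridors overlap, the higher risk code wins.
    """
    code = {"high": 3.0, "medium": 2.0, "low": 1.0}
    out = np.zeros(grid.shape)
    for cor in corridors:
        v = code.get(cor.risk, 0.0)
        for r, c in cor.lcp_cells:
            out[r, c] = max(out[r, c], v)
    out[np.isnan(grid.values)] = np.nan
    return grid.copy_with(out, kind="categorical", name="invasion_risk")
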