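"""Predictor preparation: grid alignment, DEM-corrected distances, VIF filtering.

Distance-to-feature rasters use *surface* distance: each grid step costs the
hypotenuse of its planar length and the elevation change along it, so rough
terrain yields longer distances than the map-plane would suggest.  Collinear
predictors are pruned by iterated variance-inflation-factor (VIF)
elimination: the worst offender is dropped and VIFs recomputed until all
survivors fall at or below the threshold (default 10, the conventional
cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .raster import RasterLayer

__all__ = [
    "EnvStack",
    "VifReport",
    "VifFilter",
    "resample_to_grid",
    "surface_distance",
    "vif_filter",
    "grid_edges",
    "grid_dijkstra",
]

SQRT2 = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# EnvStack
# ---------------------------------------------------------------------------
@dataclass
class EnvStack:
    """An ordered, grid-aligned collection of named predictor layers."""

    layers: dict[str, RasterLayer]

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(names) != len(set(names)):
            raise ValueError("duplicate layer names")
        ref = next(iter(self.layers.values()))
        for name, lyr in self.layers.items():
            if not lyr.same_grid(ref):
                raise ValueError(f"layer {name!r} is not on the shared grid")
            lyr.name = lyr.name or name

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def kinds(self) -> dict[str, str]:
        return {n: l.kind for n, l in self.layers.items()}

    @property
    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "continuous"]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "categorical"]

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def grid(self) -> RasterLayer:
        """A reference layer carrying the shared grid geometry."""
        return next(iter(self.layers.values()))

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer (complete cases)."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers.values():
            mask &= lyr.valid_mask
        return mask

    def table(self, rows: np.ndarray, cols: np.ndarray):
        """Predictor matrix (pandas DataFrame) at the given cells."""
        import pandas as pd

        data = {n: l.values[rows, cols] for n, l in self.layers.items()}
        return pd.DataFrame(data)

    def subset(self, names: list[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------
def resample_to_grid(layer: RasterLayer, target: RasterLayer) -> RasterLayer:
    """Regrid ``layer`` onto ``target``'s geometry.

    Continuous layers are interpolated bilinearly; categorical layers by
    nearest neighbor (so no new class codes can appear).  Cells whose
    bilinear stencil touches nodata, or that fall outside the source extent,
    come back as nodata.
    """
    if layer.kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown layer kind {layer.kind!r}")

    nrows_t, ncols_t = target.shape
    # world coordinates of target cell centers
    cols_t, rows_t = np.meshgrid(np.arange(ncols_t), np.arange(nrows_t))
    x = target.origin[0] + (cols_t + 0.5) * target.cell_size
    y = target.origin[1] + (nrows_t - rows_t - 0.5) * target.cell_size
    # fractional source indices of those centers
    nrows_s = layer.shape[0]
    fc = (x - layer.origin[0]) / layer.cell_size - 0.5
    fr = nrows_s - 0.5 - (y - layer.origin[1]) / layer.cell_size

    inside = (
        (fc > -0.5 - 1e-9) & (fc < layer.shape[1] - 0.5 + 1e-9)
        & (fr > -0.5 - 1e-9) & (fr < nrows_s - 0.5 + 1e-9)
    )
    if not inside.any():
        raise ValueError("source and target extents do not overlap")

    order = 1 if layer.kind == "continuous" else 0
    src = layer.values
    valid = layer.valid_mask.astype(float)
    filled = np.where(layer.valid_mask, src, 0.0)
    coords = np.stack([fr.ravel(), fc.ravel()])
    out = ndimage.map_coordinates(filled, coords, order=order, mode="nearest")
    wt = ndimage.map_coordinates(valid, coords, order=order, mode="nearest")
    out = out.reshape(target.shape)
    wt = wt.reshape(target.shape)
    out[(wt < 1.0 - 1e-9) | ~inside] = np.nan
    return RasterLayer(
        values=out,
        cell_size=target.cell_size,
        origin=target.origin,
        kind=layer.kind,
        name=layer.name,
    )


# ---------------------------------------------------------------------------
# Grid graph + Dijkstra
# ---------------------------------------------------------------------------
def grid_edges(valid: np.ndarray):
    """All 8-connected neighbor pairs among valid cells.

    Returns flat node indices ``(i, j)`` (each undirected pair once) and a
    boolean ``diagonal`` flag per pair.  Nodata cells carry no edges: they
    are impassable.
    """
    nrows, ncols = valid.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    pairs_i, pairs_j, diag = [], [], []
    # offsets covering each undirected pair exactly once
    for dr, dc, is_diag in ((0, 1, False), (1, 0, False),
                            (1, 1, True), (1, -1, True)):
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows + min(0, dr) or None)
        c1 = slice(max(0, dc), ncols + min(0, dc) or None)
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        ok = valid.ravel()[a] & valid.ravel()[b]
        pairs_i.append(a[ok])
        pairs_j.append(b[ok])
        diag.append(np.full(ok.sum(), is_diag))
    return (
        np.concatenate(pairs_i),
        np.concatenate(pairs_j),
        np.concatenate(diag),
    )


def grid_dijkstra(
    weights_per_edge: np.ndarray,
    edges: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_nodes: int,
    sources: np.ndarray,
    return_predecessors: bool = False,
):
    """Multi-source shortest paths on a weighted grid graph.

    Returns per-node minimum distance to the nearest source, and optionally
    (predecessor, attaining-source) arrays for path/allocation reconstruction.
    Unreachable nodes get ``inf``.
    """
    i, j, _ = edges
    graph = csr_matrix(
        (weights_per_edge, (i, j)), shape=(n_nodes, n_nodes)
    )
    res = dijkstra(
        graph,
        directed=False,
        indices=np.asarray(sources),
        min_only=True,
        return_predecessors=return_predecessors,
    )
    return res  # dist or (dist, predecessors, sources)


def surface_distance(
    features: np.ndarray | set, dem: RasterLayer
) -> RasterLayer:
    """Least accumulated surface distance to the nearest feature cell.

    Each grid step costs ``sqrt(planar² + Δz²)`` where planar is the cell
    size (cardinal) or cell size·√2 (diagonal).  Feature cells get 0; nodata
    cells are impassable and stay nodata.

    ``features`` is a boolean mask on the DEM grid or a set of (row, col)
    indices.
    """
    mask = _feature_mask(features, dem.shape)
    if not mask.any():
        raise ValueError("feature set is empty")
    valid = dem.valid_mask
    z = np.where(valid, dem.values, 0.0).ravel()
    i, j, diag = grid_edges(valid)
    planar = np.where(diag, dem.cell_size * SQRT2, dem.cell_size)
    w = np.sqrt(planar**2 + (z[i] - z[j]) ** 2)
    src = np.flatnonzero((mask & valid).ravel())
    if src.size == 0:
        raise ValueError("all feature cells fall on nodata")
    dist = grid_dijkstra(w, (i, j, diag), dem.values.size, src)
    out = dist.reshape(dem.shape)
    out[~valid] = np.nan
    return dem.copy_with(out, kind="continuous", name="dist")


def _feature_mask(features, shape) -> np.ndarray:
    if isinstance(features, np.ndarray) and features.dtype == bool:
        if features.shape != shape:
            raise ValueError("feature mask shape mismatch")
        return features
    mask = np.zeros(shape, dtype=bool)
    for r, c in features:
        mask[r, c] = True
    return mask


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------
@dataclass
class VifReport:
    """Outcome of iterated VIF elimination."""

    vif: dict[str, float]            # final VIF per survivor
    eliminated: list[str] = field(default_factory=list)
    eliminated_vif: dict[str, float] = field(default_factory=dict)
    threshold: float = 10.0

    @property
    def retained(self) -> list[str]:
        return list(self.vif)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"variable": n, "vif": v, "eliminated": False, "order": -1}
            for n, v in self.vif.items()
        ] + [
            {"variable": n, "vif": self.eliminated_vif[n],
             "eliminated": True, "order": k}
            for k, n in enumerate(self.eliminated)
        ]
        return pd.DataFrame(rows)


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1−R²_j) from regressing column j on the rest (+intercept)."""
    Xc = X - X.mean(axis=0)
    p = Xc.shape[1]
    out = np.empty(p)
    for jcol in range(p):
        y = Xc[:, jcol]
        ss_tot = float(y @ y)
        if p == 1:
            out[jcol] = 1.0
            continue
        A = np.delete(Xc, jcol, axis=1)
        if ss_tot <= 1e-30:  # constant column: nothing to inflate
            out[jcol] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[jcol] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    stack: EnvStack, threshold: float = 10.0, max_cells: int = 10000
) -> VifReport:
    """Iteratively eliminate continuous predictors with VIF above threshold.

    Categorical layers pass through untouched.  Perfectly collinear
    variables show VIF = inf and are eliminated first.  At each round the
    single worst variable is dropped and VIFs recomputed, so survivors are
    guaranteed to satisfy the threshold — a single pass cannot promise that.
    """
    names = stack.continuous_names
    if len(names) < 2:
        raise ValueError("need at least 2 continuous variables for VIF")
    mask = stack.valid_mask
    rows, cols = np.nonzero(mask)
    if rows.size > max_cells:  # deterministic stride subsample
        step = rows.size / max_cells
        keep = (np.arange(max_cells) * step).astype(int)
        rows, cols = rows[keep], cols[keep]
    if rows.size < len(names) + 2:
        raise ValueError("too few complete-case cells for VIF estimation")
    X = np.column_stack([stack[n].values[rows, cols] for n in names])

    active = list(range(len(names)))
    eliminated: list[str] = []
    eliminated_vif: dict[str, float] = {}
    while True:
        v = _vif_values(X[:, active])
        worst = int(np.argmax(v))
        if v[worst] > threshold and len(active) > 1:
            name = names[active[worst]]
            eliminated.append(name)
            eliminated_vif[name] = float(v[worst])
            del active[worst]
        else:
            break
    final = {names[k]: float(val) for k, val in zip(active, v)}
    return VifReport(
        vif=final,
        eliminated=eliminated,
        eliminated_vif=eliminated_vif,
        threshold=threshold,
    )


def apply_vif(stack: EnvStack, report: VifReport) -> EnvStack:
    """Drop eliminated layers from the stack (categoricals always kept)."""
    keep = [
        n for n in stack.names
        if stack[n].kind == "categorical" or n not in report.eliminated
    ]
    return stack.subset(keep)


class VifFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: drop high-VIF columns of a feature matrix.

    Operates on plain numeric arrays / DataFrames; the raster-level entry
    point is :func:`vif_filter`.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"x{k}" for k in range(arr.shape[1])]
        active = list(range(arr.shape[1]))
        order: list[str] = []
        while True:
            v = _vif_values(arr[:, active])
            worst = int(np.argmax(v))
            if v[worst] > self.threshold and len(active) > 1:
                order.append(names[active[worst]])
                del active[worst]
            else:
                break
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(arr.shape[1], dtype=bool)
        self.support_[active] = True
        self.eliminated_ = order
        self.vif_ = {names[k]: float(val) for k, val in zip(active, v)}
        return self

    def transform(self, X):
        import pandas as pd

        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]
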