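"""Least-cost-path connectivity over an inverted-suitability resistance surface.

Habitat probability p becomes resistance r = max(1 - p, ε): the more
suitable a cell, the cheaper it is to traverse (ε keeps perfect habitat
from being free).  Moving between 8-neighbors costs the mean of the two
endpoint resistances times the geometric step length — the standard GIS
cost-distance convention.  Corridors link core pairs whose cost-allocation
regions touch (the neighbor rule of corridor-mapping tools, which yields
roughly one to two corridors per core rather than all pairs), topped up
with minimum-spanning links so the corridor graph is connected whenever the
surface is passable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.sparse import csr_matrix

from .cores import CorePatch
from .prep import SQRT2, grid_dijkstra, grid_edges
from .raster import RasterLayer

__all__ = [
    "ResistanceSurface",
    "Corridor",
    "build_resistance",
    "cost_distance",
    "build_corridor_network",
    "corridor_surface",
    "corridor_mosaic",
]


@dataclass
class ResistanceSurface:
    resistance: RasterLayer
    epsilon: float = 1e-3


@dataclass
class Corridor:
    core_pair: tuple[int, int]
    lcp_cells: list[tuple[int, int]]
    cost: float
    length_km: float
    catchment_ids: set[int] = field(default_factory=set)
    risk: str = ""
    touches_confirmed: bool = False


def build_resistance(
    probability: RasterLayer, epsilon: float = 1e-3
) -> ResistanceSurface:
    """Invert habitat probability into movement resistance."""
    p = probability.values
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("probability values must lie in [0, 1]")
    r = np.where(valid, np.maximum(1.0 - p, epsilon), np.nan)
    return ResistanceSurface(
        resistance=probability.copy_with(
            r, kind="continuous", name="resistance"
        ),
        epsilon=epsilon,
    )


def _edge_weights(res: RasterLayer):
    valid = res.valid_mask
    r = np.where(valid, res.values, 0.0).ravel()
    i, j, diag = grid_edges(valid)
    step = np.where(diag, res.cell_size * SQRT2, res.cell_size)
    w = 0.5 * (r[i] + r[j]) * step
    return (i, j, diag), w, valid


def cost_distance(
    resistance: ResistanceSurface | RasterLayer,
    sources: np.ndarray | set,
) -> tuple[RasterLayer, np.ndarray]:
    """Accumulated least cost from the nearest source cell, plus backlinks.

    Returns the cost raster (inf where unreachable, nodata preserved) and a
    flat predecessor array for path reconstruction (-9999 marks sources and
    unreached cells).
    """
    res = (
        resistance.resistance
        if isinstance(resistance, ResistanceSurface)
        else resistance
    )
    edges, w, valid = _edge_weights(res)
    src = _source_indices(sources, res)
    dist, pred, _ = grid_dijkstra(
        w, edges, res.values.size, src, return_predecessors=True
    )
    cost = dist.reshape(res.shape)
    cost = np.where(valid, cost, np.nan)
    out = res.copy_with(cost, kind="continuous", name="cost")
    # keep inf as inf (copy_with casts to float; nan marks nodata only)
    return out, pred


def _source_indices(sources, res: RasterLayer) -> np.ndarray:
    ncols = res.shape[1]
    if isinstance(sources, np.ndarray) and sources.ndim == 2:
        cells = [(int(r), int(c)) for r, c in sources]
    else:
        cells = [(int(r), int(c)) for r, c in sources]
    if not cells:
        raise ValueError("source set is empty")
    valid = res.valid_mask
    flat = [r * ncols + c for r, c in cells if valid[r, c]]
    if not flat:
        raise ValueError("all source cells fall on nodata")
    return np.asarray(sorted(flat))


def _trace(pred: np.ndarray, start_flat: int) -> list[int]:
    """Follow backlinks from a node to its source; returns flat node list."""
    path = [start_flat]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return path


def _path_length_km(path: list[int], ncols: int, cell_size: float) -> float:
    total = 0.0
    for a, b in zip(path, path[1:]):
        ra, ca = divmod(a, ncols)
        rb, cb = divmod(b, ncols)
        diag = (ra != rb) and (ca != cb)
        total += cell_size * (SQRT2 if diag else 1.0)
    return total / 1000.0


def build_corridor_network(
    cores: list[CorePatch],
    resistance: ResistanceSurface,
) -> list[Corridor]:
    """One least-cost corridor per adjacent core pair.

    Candidate pairs come from cost-allocation adjacency: every cell is
    assigned to its cheapest core (ties to the lowest core id); core pairs
    whose allocation regions share a grid edge are linked.  A minimum
    spanning set over pairwise LCP costs adds any links needed to keep the
    corridor graph connected.  Core cells are zero-cost entry points.
    """
    if len(cores) < 2:
        raise ValueError("need at least 2 cores to build corridors")
    res = resistance.resistance
    nrows, ncols = res.shape
    n_nodes = res.values.size
    edges, w, valid = _edge_weights(res)

    costs = np.empty((len(cores), n_nodes))
    preds = []
    for k, core in enumerate(cores):
        src = _source_indices(core.cells, res)
        dist, pred, _ = grid_dijkstra(
            w, edges, n_nodes, src, return_predecessors=True
        )
        costs[k] = dist
        preds.append(pred)

    # cost allocation (argmin picks the lowest core index on ties)
    alloc = np.argmin(costs, axis=0).reshape(nrows, ncols)
    reachable = np.isfinite(costs.min(axis=0)).reshape(nrows, ncols) & valid
    alloc = np.where(reachable, alloc, -1)

    pairs: set[tuple[int, int]] = set()
    for shift in ((0, 1), (1, 0)):  # rook adjacency of allocation regions
        a = alloc[: nrows - shift[0], : ncols - shift[1]]
        b = alloc[shift[0]:, shift[1]:]
        diff = (a != b) & (a >= 0) & (b >= 0)
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((min(u, v), max(u, v)))

    # pairwise LCP costs for MST completion
    n = len(cores)
    pair_cost = np.full((n, n), np.inf)
    for a in range(n):
        for b in range(a + 1, n):
            tot = costs[a] + costs[b]
            m = np.nanmin(tot)
            pair_cost[a, b] = m
    finite = np.isfinite(pair_cost)
    if finite.any():
        mst = minimum_spanning_tree(
            csr_matrix(np.where(finite, pair_cost + 1e-9, 0.0))
        ).tocoo()
        for a, b in zip(mst.row, mst.col):
            pairs.add((min(a, b), max(a, b)))

    corridors: list[Corridor] = []
    for a, b in sorted(pairs):
        tot = costs[a] + costs[b]
        if not np.isfinite(np.nanmin(tot)):
            continue
        meet = int(np.nanargmin(tot))
        lcp_cost = float(tot[meet])
        half_a = _trace(preds[a], meet)[::-1]  # core a -> meeting cell
        half_b = _trace(preds[b], meet)[1:]    # meeting cell -> core b
        path = half_a + half_b
        cells = [divmod(p, ncols) for p in path]
        corridors.append(
            Corridor(
                core_pair=(cores[a].id, cores[b].id),
                lcp_cells=[(int(r), int(c)) for r, c in cells],
                cost=lcp_cost,
                length_km=_path_length_km(path, ncols, res.cell_size),
                touches_confirmed=cores[a].confirmed or cores[b].confirmed,
            )
        )
    return corridors


def corridor_mosaic(
    cores: list[CorePatch],
    resistance: ResistanceSurface,
    cutoff: float | None = None,
) -> RasterLayer:
    """Minimum corridor (permeability) value over all linked core pairs.

    Each pair's swath value is ``cost_a + cost_b - lcp_cost``; the mosaic
    takes the per-cell minimum, so 0 marks any LCP.  ``cutoff`` defaults to
    ``10 * cell_size * mean resistance`` (a cost-weighted corridor width);
    cells above it are masked.
    """
    res = resistance.resistance
    if cutoff is None:
        cutoff = 10.0 * res.cell_size * float(np.nanmean(res.values))
    corridors = build_corridor_network(cores, resistance)
    by_id = {c.id: c for c in cores}
    cost_cache: dict[int, RasterLayer] = {}

    def cost_of(cid: int) -> RasterLayer:
        if cid not in cost_cache:
            cost_cache[cid], _ = cost_distance(resistance, by_id[cid].cells)
        return cost_cache[cid]

    mosaic = np.full(res.shape, np.inf)
    for cor in corridors:
        a, b = cor.core_pair
        surf = corridor_surface(cost_of(a), cost_of(b), cor.cost,
                                cutoff=cutoff)
        v = np.where(np.isnan(surf.values), np.inf, surf.values)
        mosaic = np.minimum(mosaic, v)
    mosaic = np.where(np.isinf(mosaic), np.nan, mosaic)
    mosaic[~res.valid_mask] = np.nan
    return res.copy_with(mosaic, kind="continuous", name="permeability")


def corridor_surface(
    cost_from_a: RasterLayer,
    cost_from_b: RasterLayer,
    lcp_cost: float,
    cutoff: float | None = None,
    tol: float = 1e-6,
) -> RasterLayer:
    """Permeability swath around one LCP.

    Per-cell value ``cost_a + cost_b - lcp_cost`` measures how much longer
    the best path through that cell is than the LCP; the LCP itself scores
    0.  Cells above ``cutoff`` (if given) are masked out.
    """
    if not cost_from_a.same_grid(cost_from_b):
        raise ValueError("cost rasters are not on the same grid")
    v = cost_from_a.values + cost_from_b.values - lcp_cost
    if np.nanmin(v) < -max(tol, abs(lcp_cost) * 1e-9):
        raise ValueError(
            "negative corridor values: lcp_cost exceeds the optimum"
        )
    v = np.maximum(v, 0.0)
    if cutoff is not None:
        v = np.where(v <= cutoff, v, np.nan)
    return cost_from_a.copy_with(v, kind="continuous", name="corridor")
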