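"""Seeded synthetic study areas for the invasion-risk pipeline.

Real applications of this pipeline run on national-scale geodata (climate
surfaces, DEM derivatives, soil and land-use maps, hydrography).  This
module generates landscapes with the same statistical structure — a
spatially autocorrelated DEM partitioned into river catchments, a 13-layer
predictor stack with climatic lapse-rate gradients, DEM-corrected distance
variables and categorical mosaics, a known true habitat-suitability surface,
and presence points sampled from it — so every downstream stage (ensemble
SDM, core extraction, corridors, risk classes) can be exercised and its
parameter recovery measured against known ground truth.

Everything is a pure function of (scenario, seed): the same scenario yields
bit-identical outputs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .occurrences import OccurrenceSet
from .prep import EnvStack, surface_distance
from .raster import RasterLayer

__all__ = [
    "SyntheticScenario",
    "TrueSuitability",
    "generate_terrain",
    "generate_predictor_stack",
    "true_suitability",
    "sample_occurrences",
    "generate_scenario",
]

#: Predictor layer names (field-standard abbreviations) and their kinds.
PREDICTOR_KINDS: dict[str, str] = {
    "Bio6": "continuous",          # mean min temperature, coldest month (0.1 °C)
    "Bio12": "continuous",         # annual precipitation (mm)
    "LUType": "categorical",       # land-use type
    "DistLakes": "continuous",     # surface distance to lakes (m)
    "DistWaterc": "continuous",    # surface distance to watercourses (m)
    "DistRoadsRailw": "continuous",  # surface distance to roads/railways (m)
    "HII": "continuous",           # human impact index
    "Slope": "continuous",         # degrees
    "SoilClass": "categorical",
    "SoilText": "categorical",
    "SoilStruct": "categorical",
    "SolarRad": "continuous",      # W/m2
    "TreeDens": "continuous",      # % canopy cover
}

#: Default drivers of true suitability: a warmth-loving riparian invader —
#: milder winters (higher Bio6), proximity to watercourses, wetter climate,
#: human disturbance; closed canopy slightly unfavourable.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "Bio6": 6.0,
    "DistWaterc": -5.0,
    "Bio12": 3.0,
    "HII": 2.0,
    "TreeDens": -1.6,
}

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study area.

    Defaults mirror the analysis conditions: 100 m cells and 59 presence
    records (49 field + 10 literature-style).
    """

    grid_shape: tuple[int, int] = (60, 80)
    cell_size_m: float = 100.0
    n_presences: int = 59
    n_basins: int = 4
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    true_intercept: float = -4.0
    noise_sd: float = 0.5
    seed: int = 0
    relief_m: float = 600.0
    smoothing_cells: float = 6.0
    n_roads: int = 3
    n_lakes: int = 2
    n_classes: dict[str, int] = field(
        default_factory=lambda: {
            "LUType": 6, "SoilClass": 5, "SoilText": 4, "SoilStruct": 4
        }
    )

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 10:
            raise ValueError("grid_shape dims must be >= 10")
        if self.n_presences < 1:
            raise ValueError("n_presences must be positive")
        if self.n_basins < 2:
            raise ValueError("n_basins must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Namespaced generator: independent stream per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), stream])
        )


@dataclass
class TrueSuitability:
    """Known ground-truth habitat suitability (for parameter recovery)."""

    probability: RasterLayer
    linear_predictor: RasterLayer


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------
def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-scaled spatially autocorrelated field (smoothed white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _priority_flood_fill(dem: np.ndarray) -> np.ndarray:
    """Depression-filled DEM: every cell has a monotone non-increasing
    downhill path to the grid boundary."""
    nrows, ncols = dem.shape
    filled = np.full_like(dem, np.inf)
    visited = np.zeros(dem.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    seq = 0
    for r in range(nrows):
        for c in range(ncols):
            if r in (0, nrows - 1) or c in (0, ncols - 1):
                filled[r, c] = dem[r, c]
                heapq.heappush(heap, (dem[r, c], seq, r, c))
                seq += 1
                visited[r, c] = True
    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and not visited[rr, cc]:
                visited[rr, cc] = True
                filled[rr, cc] = max(dem[rr, cc], z)
                heapq.heappush(heap, (filled[rr, cc], seq, rr, cc))
                seq += 1
    return filled


def _watershed_labels(
    dem: np.ndarray, outlets: list[tuple[int, int]]
) -> np.ndarray:
    """Grow basins from outlet cells in elevation order (priority-flood
    watershed). Ties broken by lowest basin index for determinism."""
    nrows, ncols = dem.shape
    labels = np.zeros(dem.shape, dtype=int)
    heap: list[tuple[float, int, int, int, int]] = []
    seq = 0
    for k, (r, c) in enumerate(outlets, start=1):
        labels[r, c] = k
        heapq.heappush(heap, (dem[r, c], k, seq, r, c))
        seq += 1
    while heap:
        z, k, _, r, c = heapq.heappop(heap)
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] == 0:
                labels[rr, cc] = k
                heapq.heappush(heap, (max(dem[rr, cc], z), k, seq, rr, cc))
                seq += 1
    return labels


def _pick_outlets(
    dem: np.ndarray, n_basins: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Low boundary cells, mutually separated so basins are non-trivial."""
    nrows, ncols = dem.shape
    border = [
        (r, c)
        for r in range(nrows)
        for c in range(ncols)
        if r in (0, nrows - 1) or c in (0, ncols - 1)
    ]
    perimeter = len(border)
    min_sep = max(3, perimeter // (3 * n_basins))
    border.sort(key=lambda rc: (dem[rc], rc))
    chosen: list[tuple[int, int]] = []
    for rc in border:
        if all(
            abs(rc[0] - o[0]) + abs(rc[1] - o[1]) >= min_sep for o in chosen
        ):
            chosen.append(rc)
        if len(chosen) == n_basins:
            return chosen
    raise ValueError(
        f"grid {dem.shape} too small to host {n_basins} separated basins"
    )


def _trace_river(
    dem: np.ndarray, labels: np.ndarray, basin: int
) -> list[tuple[int, int]]:
    """Steepest-descent path from the basin's highest cell, restricted to
    the basin; monotone non-increasing in elevation by construction."""
    in_basin = labels == basin
    start = np.unravel_index(
        np.argmax(np.where(in_basin, dem, -np.inf)), dem.shape
    )
    path = [tuple(int(v) for v in start)]
    seen = {path[0]}
    nrows, ncols = dem.shape
    while True:
        r, c = path[-1]
        candidates = [
            (dem[rr, cc], rr, cc)
            for dr, dc in _NEIGHBORS8
            if 0 <= (rr := r + dr) < nrows
            and 0 <= (cc := c + dc) < ncols
            and in_basin[rr, cc]
            and (rr, cc) not in seen
            and dem[rr, cc] <= dem[r, c]
        ]
        if not candidates:
            return path
        _, rr, cc = min(candidates)
        path.append((rr, cc))
        seen.add((rr, cc))


def _rasterize_line(p0, p1, shape) -> list[tuple[int, int]]:
    n = int(2 * max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]))) + 2
    rr = np.clip(np.round(np.linspace(p0[0], p1[0], n)), 0, shape[0] - 1)
    cc = np.clip(np.round(np.linspace(p0[1], p1[1], n)), 0, shape[1] - 1)
    out, prev = [], None
    for r, c in zip(rr.astype(int), cc.astype(int)):
        if (r, c) != prev:
            out.append((r, c))
            prev = (r, c)
    return out


def generate_terrain(scenario: SyntheticScenario) -> dict:
    """DEM, slope, rivers, roads, lakes, and a catchment partition.

    The DEM is a smoothed (spatially autocorrelated) random field,
    depression-filled so that rivers — steepest-descent traces from each
    basin's highest point — are monotone non-increasing.  Catchments grow
    from boundary outlets by watershed flooding and partition the whole grid
    into ``n_basins`` contiguous regions, each holding one river.
    """
    shape = scenario.grid_shape
    rng = scenario.rng(0)
    base = _smooth_field(rng, shape, scenario.smoothing_cells)
    if scenario.relief_m > 0:
        z01 = (base - base.min()) / (base.max() - base.min())
        dem0 = z01 * scenario.relief_m
    else:
        dem0 = np.zeros(shape)
    dem = _priority_flood_fill(dem0)

    outlets = _pick_outlets(dem, scenario.n_basins, rng)
    labels = _watershed_labels(dem, outlets)

    rivers: set[tuple[int, int]] = set()
    for k in range(1, scenario.n_basins + 1):
        rivers.update(_trace_river(dem, labels, k))

    roads: set[tuple[int, int]] = set()
    nrows, ncols = shape
    for _ in range(scenario.n_roads):
        if rng.random() < 0.5:  # west-east
            p0 = (rng.integers(0, nrows), 0)
            p1 = (rng.integers(0, nrows), ncols - 1)
        else:  # north-south
            p0 = (0, rng.integers(0, ncols))
            p1 = (nrows - 1, rng.integers(0, ncols))
        roads.update(_rasterize_line(p0, p1, shape))

    lakes: set[tuple[int, int]] = set()
    flat = np.argsort(dem, axis=None)
    low_cells = [np.unravel_index(i, shape) for i in flat[: nrows * ncols // 4]]
    for _ in range(scenario.n_lakes):
        cr, cc = low_cells[rng.integers(0, len(low_cells))]
        radius = int(rng.integers(1, 3))
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, ccc = cr + dr, cc + dc
                if 0 <= rr < nrows and 0 <= ccc < ncols and dr * dr + dc * dc <= radius * radius:
                    lakes.add((rr, ccc))

    cs = scenario.cell_size_m
    gy, gx = np.gradient(dem, cs)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    make = lambda v, kind, name: RasterLayer(
        v, cell_size=cs, origin=(0.0, 0.0), kind=kind, name=name
    )
    return {
        "dem": make(dem, "continuous", "DEM"),
        "slope": make(slope, "continuous", "Slope"),
        "rivers": rivers,
        "roads": roads,
        "lakes": lakes,
        "catchments": make(labels.astype(float), "categorical", "Catchments"),
    }


# ---------------------------------------------------------------------------
# Predictor stack
# ---------------------------------------------------------------------------
def _voronoi_classes(
    rng: np.random.Generator, shape, k: int
) -> np.ndarray:
    """Nearest-seed tessellation into k classes (codes 1..k)."""
    nrows, ncols = shape
    seeds = np.column_stack(
        [rng.integers(0, nrows, size=k), rng.integers(0, ncols, size=k)]
    )
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    return np.argmin(d2, axis=-1).astype(float) + 1.0


def generate_predictor_stack(
    scenario: SyntheticScenario, terrain: dict
) -> EnvStack:
    """The 13-layer predictor stack on the scenario grid.

    Climatic layers follow lapse-rate analogues of the DEM (Bio6 falls,
    Bio12 rises, SolarRad falls with elevation) plus autocorrelated noise
    scaled by ``noise_sd``; distance layers are DEM-corrected surface
    distances to the terrain's rivers, lakes and roads; categorical layers
    are Voronoi mosaics; HII and TreeDens are bounded indices.
    """
    for key in ("dem", "slope", "rivers", "roads", "lakes"):
        if key not in terrain:
            raise ValueError(f"terrain is missing component {key!r}")
    dem: RasterLayer = terrain["dem"]
    shape = dem.shape
    rng = scenario.rng(1)
    rel = dem.values.max() - dem.values.min()
    z01 = (dem.values - dem.values.min()) / (rel if rel > 0 else 1.0)

    def noisy(amplitude: float) -> np.ndarray:
        return (
            scenario.noise_sd
            * amplitude
            * _smooth_field(rng, shape, scenario.smoothing_cells / 2)
        )

    cs = scenario.cell_size_m
    mk = lambda v, kind, name: RasterLayer(
        np.asarray(v, dtype=float), cell_size=cs, origin=(0.0, 0.0),
        kind=kind, name=name,
    )
    layers: dict[str, RasterLayer] = {}
    # 0.1 °C units: valley floors near -2.9 °C, summits near -8.9 °C
    layers["Bio6"] = mk(-29.0 - 60.0 * z01 + noisy(6.0), "continuous", "Bio6")
    layers["Bio12"] = mk(525.0 + 294.0 * z01 + noisy(30.0), "continuous", "Bio12")
    layers["LUType"] = mk(
        _voronoi_classes(rng, shape, scenario.n_classes["LUType"]),
        "categorical", "LUType",
    )
    layers["DistLakes"] = surface_distance(terrain["lakes"], dem)
    layers["DistLakes"].name = "DistLakes"
    layers["DistWaterc"] = surface_distance(terrain["rivers"], dem)
    layers["DistWaterc"].name = "DistWaterc"
    layers["DistRoadsRailw"] = surface_distance(terrain["roads"], dem)
    layers["DistRoadsRailw"].name = "DistRoadsRailw"
    hii = 35.0 + 12.0 * _smooth_field(rng, shape, scenario.smoothing_cells)
    layers["HII"] = mk(np.clip(hii, 14.0, 56.0), "continuous", "HII")
    layers["Slope"] = terrain["slope"]
    for cat in ("SoilClass", "SoilText", "SoilStruct"):
        layers[cat] = mk(
            _voronoi_classes(rng, shape, scenario.n_classes[cat]),
            "categorical", cat,
        )
    layers["SolarRad"] = mk(
        1405.0 - 210.0 * z01 + noisy(15.0), "continuous", "SolarRad"
    )
    tree = 45.0 + 25.0 * _smooth_field(rng, shape, scenario.smoothing_cells)
    layers["TreeDens"] = mk(np.clip(tree, 0.0, 100.0), "continuous", "TreeDens")
    stack = EnvStack(layers)
    assert set(stack.names) == set(PREDICTOR_KINDS)
    return stack


# ---------------------------------------------------------------------------
# Truth + occurrences
# ---------------------------------------------------------------------------
def true_suitability(
    scenario: SyntheticScenario, stack: EnvStack
) -> TrueSuitability:
    """Logistic ground truth over z-scored continuous predictors."""
    grid = stack.grid
    lp = np.full(grid.shape, float(scenario.true_intercept))
    for name, coef in scenario.true_coefficients.items():
        if name not in stack:
            raise ValueError(f"true_coefficients references unknown layer {name!r}")
        v = stack[name].values
        mu, sd = np.nanmean(v), np.nanstd(v)
        z = (v - mu) / (sd if sd > 0 else 1.0)
        lp = lp + coef * np.where(np.isnan(z), 0.0, z)
    lp[~stack.valid_mask] = np.nan
    prob = expit(lp)
    return TrueSuitability(
        probability=grid.copy_with(prob, kind="continuous", name="true_prob"),
        linear_predictor=grid.copy_with(lp, kind="continuous", name="true_lp"),
    )


def sample_occurrences(
    scenario: SyntheticScenario, truth: TrueSuitability
) -> OccurrenceSet:
    """Draw presence cells without replacement, weighted by suitability."""
    prob = truth.probability
    valid = prob.valid_mask
    flat = np.flatnonzero(valid.ravel())
    w = prob.values.ravel()[flat]
    pos = w > 0
    if scenario.n_presences > int(pos.sum()):
        raise ValueError(
            f"n_presences={scenario.n_presences} exceeds the "
            f"{int(pos.sum())} cells with nonzero suitability"
        )
    rng = scenario.rng(3)
    chosen = rng.choice(
        flat, size=scenario.n_presences, replace=False, p=w / w.sum()
    )
    pts = []
    for f in sorted(int(v) for v in chosen):
        r, c = divmod(f, prob.shape[1])
        x, y = prob.cell_center(r, c)
        pts.append((x, y, "synthetic"))
    return OccurrenceSet(pts)


def generate_scenario(scenario: SyntheticScenario) -> dict:
    """Full bundle: terrain, predictor stack, truth, occurrences."""
    terrain = generate_terrain(scenario)
    stack = generate_predictor_stack(scenario, terrain)
    truth = true_suitability(scenario, stack)
    occ = sample_occurrences(scenario, truth)
    return {
        "scenario": scenario,
        "terrain": terrain,
        "stack": stack,
        "truth": truth,
        "occurrences": occ,
    }
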