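"""End-to-end orchestration: simulate -> prep -> fit -> cores -> corridors -> risk.

A single :class:`RunConfig` carries every tunable with its conventional
default (100 m cells, 10,000 pseudo-absences, 75% calibration, 10
repetitions, AUC gate 0.75, 1 km² core threshold, VIF threshold 10, risk
breakpoints 1 / 2-5 / >=6) and one top-level seed from which every
stochastic stage derives a namespaced sub-seed.  Identical config + seed
gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from . import cores as cores_mod
from . import ensemble as ens_mod
from . import risk as risk_mod
from . import synthetic as syn
from .prep import apply_vif, vif_filter
from .raster import RasterLayer

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("invasipath")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline failed at stage {stage!r}: {original}")

    def record(self) -> dict:
        return {
            "stage": self.stage,
            "error": type(self.original).__name__,
            "message": str(self.original),
        }


@dataclass
class RunConfig:
    # synthetic scenario
    grid_shape: tuple[int, int] = (60, 80)
    cell_size_m: float = 100.0
    n_presences: int = 59
    n_basins: int = 4
    noise_sd: float = 0.5
    # predictor prep
    vif_threshold: float = 10.0
    # ensemble
    n_pseudo_absences: int = 10000
    cap_pseudo_to_available: bool = True
    n_replicates: int = 10
    calibration_fraction: float = 0.75
    auc_gate: float = 0.75
    weighting: str = "auc"
    algorithms: tuple[str, ...] = ens_mod.ALGORITHMS
    compute_contributions: bool = True
    # cores
    min_core_area_km2: float = 1.0
    core_connectivity: int = 8
    # connectivity
    resistance_epsilon: float = 1e-3
    # risk breakpoints (echoed; the rule itself is 1 / 2-5 / >=6)
    risk_high_max_catchments: int = 1
    risk_medium_max_catchments: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["algorithms"] = list(self.algorithms)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def __post_init__(self):
        if isinstance(self.grid_shape, list):
            self.grid_shape = tuple(self.grid_shape)
        if isinstance(self.algorithms, list):
            self.algorithms = tuple(self.algorithms)

    def digest(self) -> str:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["algorithms"] = list(self.algorithms)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def scenario(self) -> syn.SyntheticScenario:
        return syn.SyntheticScenario(
            grid_shape=self.grid_shape,
            cell_size_m=self.cell_size_m,
            n_presences=self.n_presences,
            n_basins=self.n_basins,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage %-10s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _provenance(cfg: RunConfig, stage: str) -> dict:
    return {
        "config_hash": cfg.digest(),
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write_corridor_geojson(
    corridors, grid: RasterLayer, path: Path
) -> None:
    features = []
    for cor in corridors:
        coords = [
            list(grid.cell_center(r, c)) for r, c in cor.lcp_cells
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "core_a": cor.core_pair[0],
                    "core_b": cor.core_pair[1],
                    "cost": cor.cost,
                    "length_km": cor.length_km,
                    "n_catchments": len(cor.catchment_ids),
                    "risk": cor.risk,
                    "touches_confirmed": cor.touches_confirmed,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis on a synthetic scenario; write all artifacts.

    Returns the in-memory results bundle (scenario, stack, ensemble result,
    cores, corridors, risk summary).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    config.to_yaml(out / "config.yaml")  # verbatim echo

    try:
        bundle = _run(config, out)
    except PipelineError as err:
        with open(out / "error.json", "w") as f:
            json.dump(err.record(), f, indent=2)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return bundle


def _run(config: RunConfig, out: Path) -> dict:
    simulate = _stage("simulate")(_simulate)
    prep = _stage("prep")(_prep)
    fit = _stage("fit")(_fit)
    cores_st = _stage("cores")(_cores)
    corridors_st = _stage("corridors")(_corridors)
    risk_st = _stage("risk")(_risk)

    scen_bundle = simulate(config, out)
    stack = prep(config, scen_bundle, out)
    result = fit(config, stack, scen_bundle, out)
    core_list = cores_st(config, result, scen_bundle, out)
    corridors = corridors_st(config, result, core_list, out)
    summary = risk_st(config, corridors, scen_bundle, out)

    with open(out / "provenance.json", "w") as f:
        json.dump(_provenance(config, "all"), f, indent=2)
    return {
        "scenario": scen_bundle,
        "stack": stack,
        "ensemble": result,
        "cores": core_list,
        "corridors": corridors,
        "risk_summary": summary,
    }


def _simulate(config: RunConfig, out: Path) -> dict:
    bundle = syn.generate_scenario(config.scenario())
    sdir = out / "scenario"
    sdir.mkdir(exist_ok=True)
    for name, layer in bundle["stack"].layers.items():
        layer.write(sdir / f"{name}.asc")
    bundle["terrain"]["dem"].write(sdir / "dem.asc")
    bundle["terrain"]["catchments"].write(sdir / "catchments.asc")
    bundle["truth"].probability.write(sdir / "true_suitability.asc")
    bundle["occurrences"].write_csv(sdir / "occurrences.csv")
    bundle["occurrences"].write_geojson(sdir / "occurrences.geojson")
    log.info("simulate: %d presences on %s grid",
             len(bundle["occurrences"]), config.grid_shape)
    return bundle


def _prep(config: RunConfig, bundle: dict, out: Path):
    stack = bundle["stack"]
    report = vif_filter(stack, threshold=config.vif_threshold)
    report.to_frame().to_csv(out / "vif_report.csv", index=False)
    if report.eliminated:
        log.info("VIF eliminated: %s", report.eliminated)
    return apply_vif(stack, report)


def _fit(config: RunConfig, stack, bundle: dict, out: Path):
    n_pseudo = config.n_pseudo_absences
    n_eligible = int(stack.valid_mask.sum()) - len(bundle["occurrences"])
    if config.cap_pseudo_to_available and n_pseudo > n_eligible:
        log.info("capping pseudo-absences %d -> %d eligible cells",
                 n_pseudo, n_eligible)
        n_pseudo = n_eligible
    result = ens_mod.fit_sdm_ensemble(
        stack,
        bundle["occurrences"],
        n_pseudo_absences=n_pseudo,
        n_replicates=config.n_replicates,
        calibration_fraction=config.calibration_fraction,
        auc_gate=config.auc_gate,
        weighting=config.weighting,
        algorithms=config.algorithms,
        compute_contributions=config.compute_contributions,
        seed=config.seed,
    )
    result.probability.write(out / "probability.asc")
    result.binary.write(out / "binary.asc")
    result.metrics_table().to_csv(
        out / "metrics.csv", index=False, float_format="%.4f"
    )
    if result.contributions:
        import pandas as pd

        pd.DataFrame(
            sorted(result.contributions.items()),
            columns=["variable", "contribution_pct"],
        ).to_csv(out / "contributions.csv", index=False, float_format="%.2f")
    log.info("fit: retained %s, ensemble AUC %.3f",
             list(result.weights), result.metrics.auc)
    return result


def _cores(config: RunConfig, result, bundle: dict, out: Path):
    labeled, cores = cores_mod.extract_cores(
        result.binary,
        occurrences=bundle["occurrences"],
        min_area_km2=config.min_core_area_km2,
        connectivity=config.core_connectivity,
    )
    labeled.write(out / "cores.asc")
    cores_mod.cores_table(cores).to_csv(
        out / "cores.csv", index=False, float_format="%.4f"
    )
    log.info("cores: %d (confirmed %d)", len(cores),
             sum(c.confirmed for c in cores))
    if len(cores) < 2:
        raise RuntimeError(
            f"only {len(cores)} core(s) above {config.min_core_area_km2} km2; "
            "corridor analysis needs at least 2"
        )
    return cores


def _corridors(config: RunConfig, result, cores, out: Path):
    surface = conn.build_resistance(
        result.probability, epsilon=config.resistance_epsilon
    )
    surface.resistance.write(out / "resistance.asc")
    corridors = conn.build_corridor_network(cores, surface)
    conn.corridor_mosaic(cores, surface).write(out / "permeability.asc")
    log.info("corridors: %d", len(corridors))
    return corridors


def _risk(config: RunConfig, corridors, bundle: dict, out: Path):
    catch = bundle["terrain"]["catchments"]
    risk_mod.classify_corridors(corridors, catch)
    summary = risk_mod.summarize(corridors)
    summary.to_frame().to_csv(
        out / "risk_summary.csv", index=False, float_format="%.4f"
    )
    _write_corridor_geojson(
        corridors, catch, out / "corridors.geojson"
    )
    risk_mod.risk_raster(corridors, catch).write(out / "risk_map.asc")
    with open(out / "risk_report.txt", "w") as fh:
        fh.write(summary.to_frame().to_string(index=False))
        fh.write("\n")
    log.info("risk: %s", {
        k: v.count for k, v in summary.per_class.items()
    })
    return summary
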