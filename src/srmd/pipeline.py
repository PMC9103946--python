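"""Staged orchestration of the full disturbance-identification workflow.

Stages (mirroring the method's own sequence):

    simulate -> fvc -> drivers -> train -> noise -> attribute -> srmd -> metrics

Every stage consumes and produces only documented interface files inside one
run directory, so stages can be re-run independently:

    scene/          synthetic fixture (GeoTIFF reflectance + DEM, GeoJSON
                    boundaries, CSV activity/meteorology, YAML truth sidecar)
    fvc/            per-year FVC GeoTIFFs from the NDVI max composite
    drivers/        per-year normalized driver GeoTIFFs + meta.yaml
    models/         per-year network checkpoints + accuracy.csv + training_log.csv
    noise/          pooled virtual-contribution samples + summary CSVs
    contributions/  per-factor C and W GeoTIFFs for the tested year
    srmd/           srmd_mask.tif (1 = disturbed)
    metrics/        distance/stats/sector CSVs
    manifest.yaml   config snapshot, checksums, stage timings, outputs

Stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from .attribution import (
    compute_contributions,
    fit_noise,
    significance_mask,
    virtual_contribution,
)
from .config import StudyConfig, get_logger, save_config
from .drivers import FACTOR_IDS, ActivityRecord, DriverStack, build_driver_stack
from .fvc import FVCEndpoints, ReflectancePair, compute_fvc, compute_ndvi, max_composite
from .grid import Grid, RegionMask, read_grid, write_grid
from .gwann import evaluate_accuracy, load_model, predict, save_model, train
from .metrics import summarize_srmd
from .scene import SceneConfig, generate_scene, write_scene

__all__ = ["RunManifest", "run_all", "STAGES"]

logger = get_logger("srmd.pipeline")

STAGES = (
    "simulate", "fvc", "drivers", "train", "noise", "attribute", "srmd", "metrics"
)


@dataclass
class RunManifest:
    """Provenance of one run: every output traceable to a config and seed."""

    seed: int
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)     # path -> sha256
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "config": self.config,
                    "stage_seconds": self.stage_seconds,
                    "inputs": self.inputs,
                    "outputs": sorted(self.outputs),
                },
                fh, sort_keys=False,
            )
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} missing: {path}")
    return path


# ---------------------------------------------------------------------------
# Scene fixture access
# ---------------------------------------------------------------------------

def _load_boundaries(scene_dir: Path) -> dict[str, object]:
    path = _require(scene_dir / "boundaries.geojson", "boundary GeoJSON")
    with open(path) as fh:
        collection = json.load(fh)
    return {
        feat["properties"]["name"]: shape(feat["geometry"])
        for feat in collection["features"]
    }


def _load_activity(scene_dir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(scene_dir / "activity.csv", "activity series"))


def _load_truth_sidecar(scene_dir: Path) -> dict:
    with open(_require(scene_dir / "truth.yaml", "truth sidecar")) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(out_dir: Path, scene_config: SceneConfig) -> Path:
    scene_dir = out_dir / "scene"
    bundle = generate_scene(scene_config)
    write_scene(bundle, scene_dir)
    return scene_dir


def stage_fvc(out_dir: Path) -> Path:
    """Reflectance snapshots -> NDVI -> per-year max composite -> FVC."""
    scene_dir = _require(out_dir / "scene", "scene directory")
    truth = _load_truth_sidecar(scene_dir)
    endpoints = FVCEndpoints(**truth["endpoints"])
    activity = _load_activity(scene_dir)
    fvc_dir = out_dir / "fvc"
    fvc_dir.mkdir(parents=True, exist_ok=True)
    for year in activity["year"]:
        nir_paths = sorted(scene_dir.glob(f"nir_{year}_*.tif"))
        if not nir_paths:
            raise FileNotFoundError(f"no reflectance snapshots for year {year}")
        ndvi_stack = []
        for nir_path in nir_paths:
            red_path = _require(
                scene_dir / nir_path.name.replace("nir_", "red_"), "red band"
            )
            pair = ReflectancePair(nir=read_grid(nir_path), red=read_grid(red_path))
            ndvi_stack.append(compute_ndvi(pair))
        composite = max_composite(ndvi_stack)
        write_grid(compute_fvc(composite, endpoints), fvc_dir / f"fvc_{year}.tif")
    return fvc_dir


def stage_drivers(out_dir: Path) -> Path:
    """Spatialize and normalize the five factors for every year."""
    scene_dir = _require(out_dir / "scene", "scene directory")
    activity = _load_activity(scene_dir)
    boundaries = _load_boundaries(scene_dir)
    dem = read_grid(_require(scene_dir / "dem.tif", "DEM"))
    grid = dem.with_values(np.zeros(dem.shape))

    years = [int(y) for y in activity["year"]]
    precip = dict(zip(years, activity["precip_mm"].astype(float)))
    temp = dict(zip(years, activity["temp_c"].astype(float)))
    mining_years = [int(y) for y, m in zip(years, activity["mining"]) if m]
    if not mining_years:
        raise ValueError("no mining year in the activity series")
    records = {
        int(row.year): ActivityRecord(
            year=int(row.year),
            population=float(row.population),
            coal_production=float(row.coal_production),
            urban_boundary=boundaries["urban"],
            mine_boundary=boundaries["mine"] if row.mining else None,
        )
        for row in activity.itertuples()
    }
    # virtual factor uses the latest mining year's boundary and production
    latest = max(mining_years)
    virtual = (records[latest].coal_production, boundaries["mine"])

    drv_dir = out_dir / "drivers"
    drv_dir.mkdir(parents=True, exist_ok=True)
    meta = {}
    for year in years:
        stack = build_driver_stack(
            year, grid, dem, precip, temp, records, virtual_mining=virtual
        )
        for fid in FACTOR_IDS:
            write_grid(stack.factors[fid], drv_dir / f"x_{fid}_{year}.tif")
        meta[year] = {
            "mining_is_virtual": bool(stack.mining_is_virtual),
            "normalization_bounds": {
                k: [float(v[0]), float(v[1])]
                for k, v in stack.normalization_bounds.items()
            },
        }
    with open(drv_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return drv_dir


def _load_stacks(out_dir: Path, years: list[int] | None = None) -> dict[int, DriverStack]:
    drv_dir = _require(out_dir / "drivers", "drivers directory")
    with open(_require(drv_dir / "meta.yaml", "driver metadata")) as fh:
        meta = yaml.safe_load(fh)
    stacks = {}
    for year, info in meta.items():
        year = int(year)
        if years is not None and year not in years:
            continue
        factors = {
            fid: read_grid(_require(drv_dir / f"x_{fid}_{year}.tif", f"driver {fid}"))
            for fid in FACTOR_IDS
        }
        stacks[year] = DriverStack(
            year=year,
            factors=factors,
            normalization_bounds={
                k: tuple(v) for k, v in info["normalization_bounds"].items()
            },
            mining_is_virtual=info["mining_is_virtual"],
        )
    return stacks


def _load_fvc(out_dir: Path, years: list[int]) -> dict[int, Grid]:
    fvc_dir = _require(out_dir / "fvc", "fvc directory")
    return {y: read_grid(_require(fvc_dir / f"fvc_{y}.tif", "FVC raster")) for y in years}


def stage_train(out_dir: Path, config: StudyConfig) -> Path:
    """Fit per-year networks on all years; write checkpoints and accuracy."""
    stacks = _load_stacks(out_dir)
    fvc = _load_fvc(out_dir, sorted(stacks))
    results = train(stacks, fvc, config)
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    log_rows, predicted = [], {}
    for year, (model, state) in results.items():
        save_model(model, models_dir / f"gwann_{year}.npz")
        predicted[year] = predict(model, stacks[year])
        log_rows += [
            {"year": year, "epoch": e + 1, "error": err}
            for e, err in enumerate(state.errors)
        ]
    pd.DataFrame(log_rows).to_csv(models_dir / "training_log.csv", index=False)
    report = evaluate_accuracy(predicted, fvc, mre_floor=config.mre_floor)
    table = report.table.copy()
    table.loc[len(table)] = {
        "year": "mean", "rmse": report.mean_rmse, "mre": report.mean_mre,
        "n": int(report.table["n"].sum()),
    }
    table.to_csv(models_dir / "accuracy.csv", index=False)
    return models_dir


def stage_noise(out_dir: Path, config: StudyConfig) -> Path:
    """Virtual contributions over the no-mining years -> pooled noise model."""
    stacks = _load_stacks(out_dir)
    nm_years = sorted(y for y, s in stacks.items() if s.mining_is_virtual)
    if not nm_years:
        raise ValueError("no no-mining years with a virtual mining factor")
    fvc = _load_fvc(out_dir, nm_years)
    vw = virtual_contribution({y: stacks[y] for y in nm_years}, fvc, config)
    noise_dir = out_dir / "noise"
    noise_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for year, g in vw.items():
        write_grid(g, noise_dir / f"vw_mine_{year}.tif")
        rows.append(pd.DataFrame({"year": year, "vw_mine": g.valid_values()}))
    samples = pd.concat(rows, ignore_index=True)
    samples.to_csv(noise_dir / "noise_samples.csv", index=False)
    noise = fit_noise(samples["vw_mine"].to_numpy(), alpha=config.alpha)
    pd.DataFrame(
        [{
            "mean": noise.mean, "sd": noise.sd,
            "critical_value": noise.critical_value,
            "alpha": noise.alpha, "n": noise.n,
            "gauss_amplitude": noise.gaussian_fit[0],
            "gauss_centre": noise.gaussian_fit[1],
            "gauss_width": noise.gaussian_fit[2],
        }]
    ).to_csv(noise_dir / "noise_summary.csv", index=False)
    return noise_dir


def stage_attribute(out_dir: Path, config: StudyConfig) -> Path:
    """Contribution maps for the tested (mining) year from its checkpoint."""
    stacks = _load_stacks(out_dir)
    mining_years = sorted(y for y, s in stacks.items() if not s.mining_is_virtual)
    if not mining_years:
        raise ValueError("no mining year to attribute")
    contrib_dir = out_dir / "contributions"
    contrib_dir.mkdir(parents=True, exist_ok=True)
    models_dir = _require(out_dir / "models", "models directory")
    for year in mining_years:
        model = load_model(_require(models_dir / f"gwann_{year}.npz", "checkpoint"))
        maps = compute_contributions(
            model, stacks[year],
            bias_factor=config.bias_factor, convention=config.share_convention,
        )
        for fid in FACTOR_IDS:
            write_grid(maps.C[fid], contrib_dir / f"c_{fid}_{year}.tif")
            write_grid(maps.W[fid], contrib_dir / f"w_{fid}_{year}.tif")
    return contrib_dir


def stage_srmd(out_dir: Path, config: StudyConfig) -> Path:
    """Significance test: W_mine against the noise critical value."""
    noise_summary = pd.read_csv(
        _require(out_dir / "noise" / "noise_summary.csv", "noise summary")
    ).iloc[0]
    samples = pd.read_csv(
        _require(out_dir / "noise" / "noise_samples.csv", "noise samples")
    )
    noise = fit_noise(samples["vw_mine"].to_numpy(), alpha=float(noise_summary["alpha"]))
    stacks = _load_stacks(out_dir)
    mining_years = sorted(y for y, s in stacks.items() if not s.mining_is_virtual)
    srmd_dir = out_dir / "srmd"
    srmd_dir.mkdir(parents=True, exist_ok=True)
    for year in mining_years:
        w_mine = read_grid(
            _require(out_dir / "contributions" / f"w_mine_{year}.tif", "W_mine")
        )
        mask = significance_mask(w_mine, noise)
        write_grid(mask.to_grid(), srmd_dir / f"srmd_mask_{year}.tif")
        logger.info(
            "srmd year=%d flagged=%d/%d (V=%.4f)",
            year, mask.count(), mask.values.size, noise.critical_value,
        )
    return srmd_dir


def stage_metrics(out_dir: Path, config: StudyConfig, buffer_km: float = 3.0) -> Path:
    """Distance, buffer and direction summaries of each identified SRMD."""
    scene_dir = _require(out_dir / "scene", "scene directory")
    boundaries = _load_boundaries(scene_dir)
    metrics_dir = out_dir / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)
    for mask_path in sorted((out_dir / "srmd").glob("srmd_mask_*.tif")):
        year = int(mask_path.stem.rsplit("_", 1)[1])
        g = read_grid(mask_path)
        mask = RegionMask(
            values=g.values > 0.5, cell_size_m=g.cell_size_m,
            origin_xy=g.origin_xy, crs_label=g.crs_label,
        )
        if mask.count() == 0:
            logger.info("metrics year=%d: empty SRMD, nothing to measure", year)
            continue
        result = summarize_srmd(mask, boundaries["mine"], buffer_km=buffer_km)
        pd.DataFrame(
            {"distance_km": result.boundary_distances_km}
        ).to_csv(metrics_dir / f"boundary_distances_{year}.csv", index=False)
        stats = dict(result.stats)
        stats["buffer_km"] = buffer_km
        stats["buffer_fraction"] = result.buffer_fraction
        pd.DataFrame([stats]).to_csv(metrics_dir / f"stats_{year}.csv", index=False)
        result.direction_ranges.to_csv(
            metrics_dir / f"directions_{year}.csv", index=False
        )
    return metrics_dir


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_all(
    config: StudyConfig,
    out_dir: str | Path,
    scene_config: SceneConfig | None = None,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Execute the pipeline end to end and write a run manifest.

    With a ``scene_config`` the run is self-contained (the ``simulate``
    stage writes its own inputs); otherwise ``out_dir/scene`` must already
    hold the documented fixture files. Idempotent under a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=config.to_dict())

    known = set(STAGES)
    if set(stages) - known:
        raise ValueError(f"unknown stages: {sorted(set(stages) - known)}")

    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate" and scene_config is None:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                stage_simulate(out_dir, scene_config)
            elif stage == "fvc":
                stage_fvc(out_dir)
            elif stage == "drivers":
                stage_drivers(out_dir)
            elif stage == "train":
                stage_train(out_dir, config)
            elif stage == "noise":
                stage_noise(out_dir, config)
            elif stage == "attribute":
                stage_attribute(out_dir, config)
            elif stage == "srmd":
                stage_srmd(out_dir, config)
            elif stage == "metrics":
                stage_metrics(out_dir, config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest.stage_seconds[stage] = round(dt, 3)
        logger.info("stage %s done in %.1fs", stage, dt)

    scene_dir = out_dir / "scene"
    if scene_dir.exists():
        for p in sorted(scene_dir.glob("*")):
            if p.is_file():
                manifest.inputs[str(p.relative_to(out_dir))] = _sha256(p)
    manifest.outputs = [
        str(p.relative_to(out_dir))
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and "scene" not in p.parts
    ]
    save_config(config, out_dir / "config_used.yaml")
    manifest.write(out_dir / "manifest.yaml")
    return manifest
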