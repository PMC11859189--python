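"""End-to-end orchestration: simulate -> correct -> matchup -> calibrate -> map -> compare.

The pipeline runs the whole retrieval workflow under one declarative
configuration with a single seed, writing every product (scenes,
matchup database, ranked algorithm tables, thematic maps, comparison
tables) plus a JSON run report with counts, a file manifest and a
reproducibility block (seed and config hash).

In simulation mode the field campaign is read off the simulated truth
rasters at randomly chosen water points, so the matchup database is
exactly consistent with the synthetic scenes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .calibration import rank_indices
from .mapping import apply_model, compare_sensors, water_mask
from .matchup import build_matchups, matchups_to_frame
from .radiometry import dn_to_radiance, invert_surface_reflectance
from .registry import get_model
from .samples import FieldSample, VARIABLES, read_samples, write_samples
from .synthetic import (
    CAMPAIGN_DATES,
    SimulationConfig,
    default_atmosphere,
    default_calibration,
    simulate_scene,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("lagoonwq")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    workdir: str = "lagoonwq_run"
    seed: int = 0
    simulate: bool = True
    n_samples: int = 22
    scene_shape: tuple[int, int] = (120, 120)
    water_fraction: float = 0.7
    noise_cv: float = 0.02
    samples_csv: str | None = None
    scene_paths: list[str] = field(default_factory=list)
    max_lag_days: int = 3
    k_folds: int = 10
    mask_threshold: float = 0.2
    sensor: str = "PerúSAT-1"
    variables: list[str] = field(default_factory=lambda: list(VARIABLES))
    do_calibrate: bool = True
    do_map: bool = True
    do_compare: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scene_shape" in raw:
            raw["scene_shape"] = tuple(raw["scene_shape"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _choose_points(
    water: np.ndarray, n: int, rng: np.random.Generator, margin: int = 20
) -> list[tuple[int, int]]:
    rows, cols = water.shape
    interior = np.zeros_like(water)
    interior[margin:-margin, margin:-margin] = True
    candidates = np.argwhere(water & interior)
    if len(candidates) < n:
        candidates = np.argwhere(water)
    idx = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    return [tuple(rc) for rc in candidates[idx]]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run report dict."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    atmosphere = default_atmosphere()
    calibration = default_calibration(atmosphere)

    # ---- simulate ---------------------------------------------------
    scenes_dn: dict[_dt.date, object] = {}
    samples: list[FieldSample] = []
    points: dict[str, tuple[float, float]] = {}
    if config.simulate:
        try:
            rng = np.random.default_rng([config.seed, 100])
            per_date = np.full(len(CAMPAIGN_DATES), config.n_samples // len(CAMPAIGN_DATES))
            per_date[: config.n_samples % len(CAMPAIGN_DATES)] += 1
            pid = 0
            for i, date in enumerate(CAMPAIGN_DATES):
                sim = SimulationConfig(
                    n_samples=max(config.n_samples, 2),
                    seed=config.seed + i,
                    noise_cv=config.noise_cv,
                    scene_shape=config.scene_shape,
                    water_fraction=config.water_fraction,
                )
                bundle = simulate_scene(sim, atmosphere, calibration, date=date)
                scenes_dn[date] = bundle.scene
                path = workdir / f"scene_{date.isoformat()}_dn.tif"
                _io.write_scene(bundle.scene, path)
                manifest.append(str(path))
                for r, c in _choose_points(bundle.water_mask, int(per_date[i]), rng):
                    pid += 1
                    point_id = f"P{pid:03d}"
                    x0, dx, y0, dy = bundle.scene.transform
                    points[point_id] = (x0 + (c + 0.5) * dx, y0 + (r + 0.5) * dy)
                    samples.append(
                        FieldSample(
                            point_id=point_id,
                            campaign_date=date,
                            **{v: float(bundle.truth[v][r, c]) for v in VARIABLES},
                        )
                    )
            spath = workdir / "field_samples.csv"
            write_samples(samples, spath)
            manifest.append(str(spath))
            report["stages"].append({"stage": "simulate", "n_samples": len(samples),
                                     "n_scenes": len(scenes_dn)})
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
    else:
        if not config.samples_csv or not config.scene_paths:
            raise PipelineError("simulate", "simulation disabled but no inputs given")
        samples = read_samples(config.samples_csv)
        for p in config.scene_paths:
            sc = _io.read_scene(p)
            scenes_dn[sc.date] = sc

    # ---- correct ----------------------------------------------------
    try:
        scenes_refl = {}
        masks = {}
        for date, sc in scenes_dn.items():
            refl = invert_surface_reflectance(dn_to_radiance(sc, calibration), atmosphere)
            scenes_refl[date] = refl
            masks[date] = water_mask(refl, config.mask_threshold)
        report["stages"].append(
            {
                "stage": "correct",
                "n_scenes": len(scenes_refl),
                "water_px": {d.isoformat(): int(m.sum()) for d, m in masks.items()},
            }
        )
    except ValueError as exc:
        raise PipelineError("correct", str(exc)) from exc

    # ---- matchup ----------------------------------------------------
    try:
        records, unpaired = build_matchups(
            scenes_refl, samples, points, masks, max_lag_days=config.max_lag_days
        )
        mframe = matchups_to_frame(records)
        mpath = workdir / "matchups.csv"
        mframe.to_csv(mpath, index=False)
        manifest.append(str(mpath))
        report["stages"].append(
            {"stage": "matchup", "n_matchups": len(records), "n_unpaired": len(unpaired)}
        )
    except ValueError as exc:
        raise PipelineError("matchup", str(exc)) from exc

    # ---- calibrate --------------------------------------------------
    best_rows = {}
    if config.do_calibrate:
        try:
            spectra = mframe[["B1", "B2", "B3", "B4"]].to_numpy()
            for variable in config.variables:
                y = mframe[variable].to_numpy(dtype=float)
                ok = np.isfinite(y)
                if ok.sum() < config.k_folds:
                    raise ValueError(
                        f"{variable}: {int(ok.sum())} matchups < k_folds = {config.k_folds}"
                    )
                search = rank_indices(
                    spectra[ok], y[ok], k=config.k_folds, seed=config.seed
                )
                table = search.results_.drop(columns=["_spec", "_model"])
                tpath = workdir / f"ranked_{variable}.csv"
                table.head(5).to_csv(tpath)
                manifest.append(str(tpath))
                best = table.iloc[0]
                best_rows[variable] = {
                    "band_comb": best["band_comb"],
                    "family": best["family"],
                    "formula": best["formula"],
                    "cv_rmse": float(best["rmse"]),
                    "cv_r2": float(best["r2"]),
                }
            report["stages"].append({"stage": "calibrate", "best": best_rows,
                                     "k_folds": config.k_folds})
        except ValueError as exc:
            raise PipelineError("calibrate", str(exc)) from exc

    # ---- map --------------------------------------------------------
    if config.do_map:
        try:
            latest = max(scenes_refl)
            for variable in config.variables:
                model = get_model(config.sensor, variable)
                tmap = apply_model(scenes_refl[latest], model, masks[latest])
                tpath = workdir / f"map_{variable}_{latest.isoformat()}.tif"
                _io.write_thematic_map(tmap, tpath)
                manifest.append(str(tpath))
            report["stages"].append(
                {"stage": "map", "date": latest.isoformat(),
                 "n_maps": len(config.variables)}
            )
        except (ValueError, KeyError) as exc:
            raise PipelineError("map", str(exc)) from exc

    # ---- compare ----------------------------------------------------
    if config.do_compare and config.do_calibrate:
        try:
            spectra = mframe[["B1", "B2", "B3", "B4"]].to_numpy()
            rows = []
            for variable in config.variables:
                published = get_model(config.sensor, variable)
                pred_pub = {
                    pid: float(v)
                    for pid, v in zip(mframe["point_id"], published.predict(spectra))
                }
                y = mframe[variable].to_numpy(dtype=float)
                ok = np.isfinite(y)
                search = rank_indices(
                    spectra[ok], y[ok], k=config.k_folds, seed=config.seed
                )
                pred_new = {
                    pid: float(v)
                    for pid, v in zip(
                        mframe["point_id"][ok], search.best_estimator_.predict(spectra[ok])
                    )
                }
                rows.append(
                    compare_sensors(
                        pred_pub, pred_new, samples, variable,
                        labels=("published", "recalibrated"),
                    )
                )
            ctable = pd.concat(rows, ignore_index=True)
            cpath = workdir / "comparison.csv"
            ctable.to_csv(cpath, index=False)
            manifest.append(str(cpath))
            report["stages"].append({"stage": "compare", "n_rows": len(ctable)})
        except ValueError as exc:
            raise PipelineError("compare", str(exc)) from exc

    report["manifest"] = manifest
    rpath = workdir / "run_report.json"
    rpath.write_text(json.dumps(report, indent=2, default=str))
    return report
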