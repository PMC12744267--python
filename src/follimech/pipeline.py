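"""End-to-end pipeline: simulate -> pressure -> timelapse -> OCT ->
stress -> cohort statistics, with CSV outputs and a run log.

The configuration is a JSON-serializable dict (see ``DEFAULT_CONFIG``)
naming a cohort design and per-modality generator options. Every stage
writes its table before the next stage runs, so a failing stage leaves
partial outputs behind and is named in the log.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .presets import make_preset
from .synthetic import simulate_calibration_set, simulate_cohort
from .pressure import calibrate_surface_tension, pressure_cohort
from .timelapse import AreaSeries, area_series, detect_rupture, fit_sigmoid
from .oct_morphometry import (extract_midplane, local_thickness_map,
                              relative_antrum_volume, segment_volume,
                              thickness_distribution)
from .wall_stress import cohort_wall_stress
from .cohort_stats import apply_exclusions, rupture_summary

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline"]

log = logging.getLogger("follimech")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "follimech_run",
    "replicates": 2,
    "design": [
        {"group": "young", "timepoint_h": 0, "treatment": "control",
         "n_follicles": 3},
        {"group": "young", "timepoint_h": 8, "treatment": "control",
         "n_follicles": 3},
        {"group": "young", "timepoint_h": 0, "treatment": "mu_1mM",
         "n_follicles": 3},
        {"group": "old", "timepoint_h": 0, "treatment": "control",
         "n_follicles": 3},
    ],
    "modalities": ["interface", "timelapse", "oct"],
    "calibration": {"n_levels": 8, "noise_sd": 10.0},
    "interface": {},
    "timelapse": {"render": False},
    "oct": {"voxel_size": 4.0},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _timelapse_series(entry: dict) -> AreaSeries:
    ph = entry["timelapse"]
    if ph.payload is not None:
        return area_series(ph)
    t = ph.truth
    return AreaSeries(times_h=t["times_h"], areas_um2=t["area_series_um2"],
                      follicle_id=t.get("follicle_id"), group=t.get("group"),
                      treatment=t.get("treatment"))


def run_pipeline(config: dict | str | Path | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis on a simulated cohort.

    Parameters
    ----------
    config : dict or path to a JSON file, optional
        Missing keys fall back to ``DEFAULT_CONFIG``.
    out_dir : path, optional
        Overrides ``config["out_dir"]``.

    Returns
    -------
    dict
        ``{"tables": {name: path}, "log": path, "config": dict}``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    run_log: dict = {"package": "follimech", "version": __version__,
                     "seed": seed, "stages": [], "started": time.time()}
    tables: dict[str, Path] = {}

    def _save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# follimech {__version__} seed={seed} table={name}\n")
            df.to_csv(fh, index=False)
        tables[name] = path

    def _finish(status: str, failed_stage: str | None = None) -> None:
        run_log["status"] = status
        run_log["failed_stage"] = failed_stage
        run_log["finished"] = time.time()
        with open(out / "run_log.json", "w") as fh:
            json.dump({**run_log, "config": _jsonable(cfg)}, fh, indent=2)

    stage = "simulate"
    try:
        log.info("stage: simulate")
        design = pd.DataFrame(cfg["design"])
        cal_table = simulate_calibration_set(seed=seed, **cfg["calibration"])
        replicates = []
        for rep in range(int(cfg["replicates"])):
            phantoms, truth = simulate_cohort(
                design, seed=seed + 1000 * rep,
                modalities=tuple(cfg["modalities"]),
                **{m: cfg.get(m, {}) for m in cfg["modalities"]})
            truth = truth.assign(replicate=rep)
            replicates.append((rep, phantoms, truth))
        truth_all = pd.concat([t for _, _, t in replicates], ignore_index=True)
        _save("calibration", cal_table)
        _save("truth", truth_all)
        run_log["stages"].append(stage)

        stage = "pressure"
        log.info("stage: pressure")
        cal = calibrate_surface_tension(cal_table)
        if "interface" in cfg["modalities"]:
            parts = []
            for rep, phantoms, _ in replicates:
                df = pressure_cohort(phantoms, cal).assign(replicate=rep)
                parts.append(df)
            pressures = pd.concat(parts, ignore_index=True)
        else:
            pressures = pd.DataFrame(columns=["follicle_id", "group",
                                              "timepoint_h", "treatment",
                                              "pressure_mmhg", "replicate"])
        _save("pressures", pressures)
        run_log["stages"].append(stage)

        stage = "timelapse"
        log.info("stage: timelapse")
        tl_rows = []
        if "timelapse" in cfg["modalities"]:
            for rep, phantoms, _ in replicates:
                for entry in phantoms:
                    series = _timelapse_series(entry)
                    call = detect_rupture(series)
                    fit = fit_sigmoid(series, rupture=call)
                    t = entry["timelapse"].truth
                    tl_rows.append({
                        "follicle_id": entry["follicle_id"],
                        "replicate": rep,
                        "group": t.get("group"),
                        "timepoint_h": t.get("timepoint_h"),
                        "treatment": t.get("treatment"),
                        "ruptured": call.ruptured,
                        "rupture_time_h": call.rupture_time_h,
                        "max_drop_fraction": call.max_drop_fraction,
                        "a0": fit.a0, "amax": fit.amax, "k": fit.k,
                        "t50": fit.t50,
                        "peak_velocity_time_h": fit.peak_velocity_time,
                        "peak_area_time_h": fit.peak_area_time,
                        "fit_converged": fit.converged,
                    })
        timelapse_df = pd.DataFrame(tl_rows)
        _save("timelapse_fits", timelapse_df)
        run_log["stages"].append(stage)

        stage = "oct"
        log.info("stage: oct")
        oct_rows = []
        if "oct" in cfg["modalities"]:
            for rep, phantoms, _ in replicates:
                for entry in phantoms:
                    ph = entry["oct"]
                    masks = segment_volume(ph)
                    mid = extract_midplane(masks)
                    thick = local_thickness_map(mid.cross_section_mask == 1,
                                                mid.pixel_size)
                    dist = thickness_distribution(thick)
                    oct_rows.append({
                        "follicle_id": entry["follicle_id"],
                        "replicate": rep,
                        "group": ph.truth.get("group"),
                        "timepoint_h": ph.truth.get("timepoint_h"),
                        "treatment": ph.truth.get("treatment"),
                        "radius_um": mid.radius_um,
                        "thickness_um": dist.weighted_mean,
                        "antrum_ratio": relative_antrum_volume(masks),
                    })
        oct_df = pd.DataFrame(oct_rows)
        _save("oct_metrics", oct_df)
        run_log["stages"].append(stage)

        stage = "stress"
        log.info("stage: stress")
        if len(oct_df) and len(pressures.dropna(subset=["pressure_mmhg"])):
            stress_df = cohort_wall_stress(
                pressures.dropna(subset=["pressure_mmhg"]), oct_df)
        else:
            stress_df = pd.DataFrame()
        _save("stress", stress_df)
        run_log["stages"].append(stage)

        stage = "stats"
        log.info("stage: stats")
        if len(timelapse_df):
            merged = pressures.merge(
                timelapse_df[["follicle_id", "replicate", "ruptured"]],
                on=["follicle_id", "replicate"], how="left")
            merged["ruptured"] = merged["ruptured"].fillna(True)
            flagged = apply_exclusions(merged)
            _save("pressures_flagged", flagged)
            _save("rupture_summary",
                  rupture_summary(timelapse_df, by="treatment"))
        if len(pressures):
            _save("pressure_by_timepoint",
                  pressures.dropna(subset=["pressure_mmhg"])
                  .groupby(["group", "treatment", "timepoint_h"],
                           as_index=False)["pressure_mmhg"]
                  .agg(["mean", "std", "count"]))
        if len(oct_df):
            _save("thickness_by_timepoint",
                  oct_df.groupby(["group", "treatment", "timepoint_h"],
                                 as_index=False)[["thickness_um",
                                                  "antrum_ratio"]].mean())
        if len(stress_df):
            _save("stress_by_timepoint",
                  stress_df.groupby(["group", "treatment", "timepoint_h"],
                                    as_index=False)["stress_pa"]
                  .agg(["mean", "std", "count"]))
        run_log["stages"].append(stage)
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        _finish("failed", stage)
        raise PipelineError(stage, exc) from exc

    _finish("ok")
    return {"tables": {k: str(v) for k, v in tables.items()},
            "log": str(out / "run_log.json"), "config": cfg}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
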