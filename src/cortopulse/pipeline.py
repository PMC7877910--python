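"""Config-driven orchestration: simulate -> detect -> stats / classify / tfm.

A pipeline is a YAML document with a global ``seed``, an ``outdir`` and an
ordered ``stages`` list; each stage has a ``stage`` name, an optional
``params`` block mirroring the library function parameters, and an optional
``inputs`` block of file paths for non-simulated data.  Per-stage random
substreams are derived deterministically from the global seed, so identical
configs give byte-identical outputs and report hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .detection import assign_region, compute_hex_series, detect_pulses
from .evaluate import run_detection
from .fibers import ClassificationCriteria, classify_fibers, fraction_under_nucleus, lifetime_stats
from .hexgrid import build_hex_grid
from .stats import paired_t_test, summarize_cell
from .synthetic import (
    FiberSimParams,
    PulseSimParams,
    generate_fiber_table,
    generate_pulse_stack,
)
from .traction import GelParams, estimate_displacement, fttc, rms_traction

__all__ = ["validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("cortopulse")

KNOWN_TOP = {"seed", "outdir", "stages", "log_level"}
KNOWN_STAGES = {"simulate", "detect", "pulse_stats", "simulate_fibers", "classify_fibers", "tfm"}

_PULSE_PARAM_KEYS = {f.name for f in dataclasses.fields(PulseSimParams)} - {"seed"}
_FIBER_PARAM_KEYS = {f.name for f in dataclasses.fields(FiberSimParams)} - {"seed"}
_DETECT_KEYS = {
    "hex_radius_um",
    "threshold_ratio",
    "min_component_size",
    "min_duration_frames",
    "window_frames",
    "baseline",
}
_TFM_KEYS = {
    "young_modulus_pa",
    "poisson_ratio",
    "regularization_lambda",
    "window_px",
    "overlap",
    "pixel_size_um",
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def validate_config(path_or_dict) -> list[str]:
    """Schema and dependency check; returns a list of diagnostics (empty = valid)."""
    cfg = load_config(path_or_dict)
    diags: list[str] = []
    for key in cfg:
        if key not in KNOWN_TOP:
            diags.append(f"unknown top-level key {key!r}")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        diags.append("'stages' must be a non-empty list")
        return diags
    seen: set[str] = set()
    for idx, st in enumerate(stages):
        loc = f"stages[{idx}]"
        if not isinstance(st, dict) or "stage" not in st:
            diags.append(f"{loc}: each stage needs a 'stage' name")
            continue
        name = st["stage"]
        if name not in KNOWN_STAGES:
            diags.append(f"{loc}: unknown stage {name!r}")
            continue
        params = st.get("params", {}) or {}
        inputs = st.get("inputs", {}) or {}
        for key in st:
            if key not in {"stage", "params", "inputs"}:
                diags.append(f"{loc}: unknown stage key {key!r}")
        if name == "simulate":
            for k, v in params.items():
                if k not in _PULSE_PARAM_KEYS:
                    diags.append(f"{loc}.params: unknown key {k!r}")
            if params.get("n_frames", 1) < 1:
                diags.append(f"{loc}.params.n_frames: must be >= 1")
            for k in ("pulse_rate_in", "pulse_rate_out"):
                if params.get(k, 0) < 0:
                    diags.append(f"{loc}.params.{k}: must be >= 0")
            if params.get("amplitude_ratio", 1) < 1:
                diags.append(f"{loc}.params.amplitude_ratio: must be >= 1")
        elif name == "detect":
            for k in params:
                if k not in _DETECT_KEYS:
                    diags.append(f"{loc}.params: unknown key {k!r}")
            if params.get("threshold_ratio", 1.3) <= 0:
                diags.append(f"{loc}.params.threshold_ratio: must be > 0")
            if params.get("min_component_size", 3) < 1:
                diags.append(f"{loc}.params.min_component_size: must be >= 1")
            if "simulate" not in seen and "stack" not in inputs:
                diags.append(f"{loc}: needs a 'simulate' stage before it or inputs.stack")
            if "simulate" not in seen and "roi_mask" not in inputs:
                diags.append(f"{loc}: needs inputs.roi_mask when not simulating")
        elif name == "pulse_stats":
            if "detect" not in seen:
                diags.append(f"{loc}: needs a 'detect' stage before it")
            if "simulate" not in seen and "nucleus_mask" not in inputs:
                diags.append(f"{loc}: needs inputs.nucleus_mask when not simulating")
        elif name == "simulate_fibers":
            for k in params:
                if k not in _FIBER_PARAM_KEYS:
                    diags.append(f"{loc}.params: unknown key {k!r}")
            if params.get("n_fibers", 1) <= 0:
                diags.append(f"{loc}.params.n_fibers: must be > 0")
        elif name == "classify_fibers":
            if params.get("mode", "live") not in ("live", "fixed"):
                diags.append(f"{loc}.params.mode: must be 'live' or 'fixed'")
            if "simulate_fibers" not in seen and "table" not in inputs:
                diags.append(f"{loc}: needs a 'simulate_fibers' stage before it or inputs.table")
        elif name == "tfm":
            for k in params:
                if k not in _TFM_KEYS:
                    diags.append(f"{loc}.params: unknown key {k!r}")
            if params.get("young_modulus_pa", 26000) <= 0:
                diags.append(f"{loc}.params.young_modulus_pa: must be > 0")
            if not 0 <= params.get("poisson_ratio", 0.5) <= 0.5:
                diags.append(f"{loc}.params.poisson_ratio: must be in [0, 0.5]")
            if params.get("window_px", 32) < 16:
                diags.append(f"{loc}.params.window_px: must be >= 16")
            if not ({"stressed", "reference"} <= set(inputs)):
                diags.append(f"{loc}: needs inputs.stressed and inputs.reference")
        seen.add(name)
    for name, inputs in [
        (st.get("stage"), st.get("inputs", {}) or {})
        for st in stages
        if isinstance(st, dict)
    ]:
        for key, path in inputs.items():
            if not Path(path).exists():
                diags.append(f"stage {name!r}: input {key!r} path does not exist: {path}")
    return diags


def _hash_params(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Execute the stages of a validated config in order.

    Returns a report dict (also written to ``outdir/report.json``) with, per
    stage, the output files (with content hashes) and summary metrics.
    Raises ``ValueError`` before any stage runs if the config is invalid.
    """
    cfg = load_config(config)
    diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid config:\n" + "\n".join(diags))
    seed = int(cfg.get("seed", 0))
    out = Path(outdir if outdir is not None else cfg.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(cfg["stages"]))
    ]

    report: dict = {"seed": seed, "stages": []}
    ctx: dict = {}

    def record(name: str, files: dict, metrics: dict, params) -> None:
        report["stages"].append(
            {
                "stage": name,
                "param_hash": _hash_params(params),
                "outputs": {k: {"path": str(p), "sha256": cio.file_sha256(p)} for k, p in files.items()},
                "metrics": metrics,
            }
        )

    for st, st_seed in zip(cfg["stages"], stage_seeds):
        name = st["stage"]
        params = dict(st.get("params", {}) or {})
        inputs = dict(st.get("inputs", {}) or {})
        log.info("stage %s (seed %d)", name, st_seed)
        try:
            if name == "simulate":
                p = PulseSimParams(**{**params, "seed": st_seed})
                sim = generate_pulse_stack(p)
                ctx["sim"] = sim
                ctx["sim_params"] = p
                files = {}
                cio.write_stack(out / "stack.tif", sim.stack)
                cio.write_mask(out / "roi_mask.tif", sim.roi_mask)
                cio.write_mask(out / "nucleus_mask.tif", sim.nucleus_mask)
                truth = pd.DataFrame(
                    [
                        {
                            "x_um": e.center_um[0],
                            "y_um": e.center_um[1],
                            "start_frame": e.start_frame,
                            "end_frame": e.end_frame,
                            "peak_ratio": e.peak_ratio,
                            "region": e.region_label,
                        }
                        for e in sim.ground_truth
                    ]
                )
                cio.write_table(out / "pulse_ground_truth.csv", truth,
                                header_comment=f"param_hash={_hash_params(params)}")
                cio.write_json(out / "simulate_params.json", dataclasses.asdict(p))
                files = {
                    "stack": out / "stack.tif",
                    "roi_mask": out / "roi_mask.tif",
                    "nucleus_mask": out / "nucleus_mask.tif",
                    "ground_truth": out / "pulse_ground_truth.csv",
                    "params": out / "simulate_params.json",
                }
                record(name, files, {"n_true_pulses": len(sim.ground_truth)}, params)
            elif name == "detect":
                if "sim" in ctx:
                    stack = ctx["sim"].stack
                    roi = ctx["sim"].roi_mask
                    nuc = ctx["sim"].nucleus_mask
                else:
                    stack = cio.read_stack(inputs["stack"])
                    roi = cio.read_mask(inputs["roi_mask"])
                    nuc = cio.read_mask(inputs["nucleus_mask"]) if "nucleus_mask" in inputs else None
                hexr = float(params.pop("hex_radius_um", 1.0))
                baseline = params.pop("baseline", "hex_median")
                grid = build_hex_grid(roi, hexr)
                series = compute_hex_series(
                    stack, grid, baseline=baseline,
                    window_frames=params.get("window_frames"),
                )
                events = detect_pulses(series, grid, **params)
                if nuc is not None:
                    assign_region(events, nuc, grid)
                ctx.update(events=events, grid=grid, roi=roi, nucleus=nuc, stack=stack)
                df = pd.DataFrame(
                    [
                        {
                            "event_id": e.event_id,
                            "start_frame": e.start_frame,
                            "end_frame": e.end_frame,
                            "duration_frames": e.duration_frames,
                            "peak_ratio": e.peak_ratio,
                            "max_area_um2": e.max_area_um2(grid),
                            "region": e.region_label,
                        }
                        for e in events
                    ]
                )
                cio.write_table(out / "events.csv", df,
                                header_comment=f"param_hash={_hash_params(params)}")
                record(name, {"events": out / "events.csv"}, {"n_events": len(events)}, params)
            elif name == "pulse_stats":
                stack = ctx["stack"] if "stack" in ctx else ctx["sim"].stack
                nuc = ctx["nucleus"]
                roi = ctx["roi"]
                window_min = params.get("window_min", stack.duration_min)
                summ = summarize_cell(ctx["events"], nuc, roi, window_min)
                metrics = summ.as_dict()
                cio.write_json(out / "pulse_stats.json", metrics)
                record(name, {"summary": out / "pulse_stats.json"}, metrics, params)
            elif name == "simulate_fibers":
                p = FiberSimParams(**{**params, "seed": st_seed})
                table = generate_fiber_table(p)
                ctx["fiber_table"] = table
                cio.write_table(out / "fiber_table.csv", table,
                                header_comment=f"param_hash={_hash_params(params)}")
                record(name, {"table": out / "fiber_table.csv"}, {"n_fibers": len(table)}, params)
            elif name == "classify_fibers":
                table = ctx.get("fiber_table")
                if table is None:
                    table = cio.read_table(inputs["table"])
                crit = ClassificationCriteria(**params)
                labeled = classify_fibers(table, crit)
                pct, sem, n = fraction_under_nucleus(labeled)
                lt = lifetime_stats(labeled)
                metrics = {
                    "n_cortical": int(labeled["is_cortical"].sum()),
                    "percent_under_nucleus": pct,
                    "sem": sem,
                    "n_cells": n,
                    "median_lifetime_min": lt["median_min"],
                }
                cio.write_table(out / "fibers_labeled.csv", labeled,
                                header_comment=f"param_hash={_hash_params(params)}")
                cio.write_json(out / "fiber_stats.json", metrics)
                record(
                    name,
                    {"labeled": out / "fibers_labeled.csv", "stats": out / "fiber_stats.json"},
                    metrics,
                    params,
                )
            elif name == "tfm":
                stressed = cio.read_stack(inputs["stressed"], pixel_size_um=params.get("pixel_size_um"))
                reference = cio.read_stack(inputs["reference"], pixel_size_um=params.get("pixel_size_um"))
                gel = GelParams(
                    youngs_modulus_pa=params.get("young_modulus_pa", 26000.0),
                    poisson_ratio=params.get("poisson_ratio", 0.5),
                )
                disp = estimate_displacement(
                    stressed, reference,
                    window_px=int(params.get("window_px", 32)),
                    overlap=float(params.get("overlap", 0.5)),
                )
                tf = fttc(disp, gel, regularization_lambda=float(params.get("regularization_lambda", 0.0)))
                x, y = tf.node_coords_um()
                full_roi = [(x[0], y[0]), (x[-1], y[0]), (x[-1], y[-1]), (x[0], y[-1])]
                rms, flag = rms_traction(tf, full_roi)
                metrics = {"rms_traction_pa": rms, "below_floor": bool(flag)}
                grid_df = pd.DataFrame(
                    {
                        "x_um": np.tile(x, len(y)),
                        "y_um": np.repeat(y, len(x)),
                        "u_um": disp.fx.ravel(),
                        "v_um": disp.fy.ravel(),
                        "tx_pa": tf.fx.ravel(),
                        "ty_pa": tf.fy.ravel(),
                    }
                )
                cio.write_table(out / "traction_grid.csv", grid_df,
                                header_comment=f"param_hash={_hash_params(params)}")
                cio.write_json(out / "tfm_stats.json", metrics)
                record(
                    name,
                    {"grid": out / "traction_grid.csv", "stats": out / "tfm_stats.json"},
                    metrics,
                    params,
                )
        except Exception as exc:  # partial report with diagnostics
            report["stages"].append({"stage": name, "error": f"{type(exc).__name__}: {exc}"})
            report["failed"] = name
            cio.write_json(out / "report.json", report)
            raise
    cio.write_json(out / "report.json", report)
    return report
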