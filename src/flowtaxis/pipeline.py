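"""End-to-end orchestration: config validation, staged runs, artifacts.

A run is driven by a single YAML/JSON config with exactly one input mode:

* ``simulate`` — generate a cohort from a named preset (seed mandatory);
* ``tracks``   — load a pre-tracked centroid table (CSV);
* ``images``   — per-group TIFF stacks through drift correction,
  segmentation, linking and exclusion.

Stages run in order (simulate/segment -> track -> quantify -> stats ->
plot); every run writes its artifacts plus a provenance record (config
hash, seed, package versions) into ``out_dir``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import estimate_drift, apply_drift, read_stack, segment_stack
from .metrics import (ArrestRule, DirectionRule, Window, arrest_rule_from_static,
                      ensemble_speed_timeseries, motility_coefficient,
                      rms_displacement_curve, summarize_group)
from .plots import plot_curves, plot_tracks
from .simulate import simulate_cohort
from .stats import compare_groups
from .tracking import apply_exclusions, link_detections
from .tracks import TrackSet, tracksets_from_csv, tracksets_to_csv

log = logging.getLogger(__name__)

MODES = ("simulate", "tracks", "images")

_TOP_KEYS = {"mode", "out_dir", "seed", "flow_angle", "windows",
             "motility_windows", "arrest", "simulate", "tracks", "images",
             "stats", "plots"}

DEFAULT_STATS_METRICS = ["displacement_um", "confinement_ratio", "arrest_coefficient"]


class ConfigError(ValueError):
    """The run configuration failed schema validation."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Validate and normalise a run config, filling defaults."""
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    mode = cfg.get("mode")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "simulate" and "seed" not in cfg:
        raise ConfigError("seed is mandatory in simulate mode")
    if "out_dir" not in cfg:
        raise ConfigError("out_dir is required")
    out = dict(cfg)
    out.setdefault("flow_angle", 0.0)
    out.setdefault("windows", [30.0, 120.0])
    out.setdefault("motility_windows", [5.0, 10.0, 20.0, 30.0, 120.0])
    out.setdefault("stats", {})
    out["stats"].setdefault("metrics", list(DEFAULT_STATS_METRICS))
    out["stats"].setdefault("transform", "auto")
    out.setdefault("plots", True)
    out.setdefault("arrest", {})
    ws = out["windows"]
    if (not isinstance(ws, (list, tuple)) or len(ws) != 2
            or not 0 < float(ws[0]) < float(ws[1])):
        raise ConfigError("windows must be [short_term_end, long_term_end] "
                          "with 0 < short < long")
    section = out.get(mode, {})
    if mode == "simulate":
        if "preset" not in section:
            raise ConfigError("simulate.preset is required")
    elif mode == "tracks":
        if "path" not in section:
            raise ConfigError("tracks.path is required")
    elif mode == "images":
        for key in ("stacks", "pixel_size", "dt", "template_box"):
            if key not in section:
                raise ConfigError(f"images.{key} is required")
    return out


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _acquire_tracksets(cfg: dict, out_dir: Path) -> dict[str, TrackSet]:
    mode = cfg["mode"]
    flow_angle = float(cfg["flow_angle"])
    if mode == "simulate":
        sim = cfg["simulate"]
        tracksets = simulate_cohort(sim["preset"], sim.get("overrides"),
                                    seed=int(cfg["seed"]), flow_angle=flow_angle)
        tracksets_to_csv(tracksets, out_dir / "tracks.csv")
        return tracksets
    if mode == "tracks":
        return tracksets_from_csv(cfg["tracks"]["path"], flow_angle=flow_angle)
    # images mode
    sec = cfg["images"]
    seg_kw = dict(sec.get("segmentation", {}))
    link_kw = dict(sec.get("linking", {}))
    tracksets = {}
    det_tables, excl_tables = [], []
    for label, path in sec["stacks"].items():
        stack = read_stack(path, pixel_size=float(sec["pixel_size"]),
                           dt=float(sec["dt"]))
        drift = estimate_drift(stack, tuple(sec["template_box"]),
                               search_radius=int(sec.get("search_radius", 20)))
        corrected = apply_drift(stack, drift)
        detections = segment_stack(corrected, **seg_kw)
        detections.insert(0, "group", label)
        det_tables.append(detections)
        raw = link_detections(detections, dt=stack.dt, **link_kw)
        n_frames = int(sec.get("n_frames", stack.n_frames))
        ts, excl = apply_exclusions(raw, n_frames, dt=stack.dt,
                                    group_label=label, flow_angle=flow_angle,
                                    gap_frames=int(link_kw.get("gap_frames", 3)))
        excl.insert(0, "group", label)
        excl_tables.append(excl)
        tracksets[label] = ts
        log.info("group %s: %d detections, %d tracks kept, %d excluded",
                 label, len(detections), ts.n, len(excl))
    pd.concat(det_tables, ignore_index=True).to_csv(out_dir / "detections.csv", index=False)
    pd.concat(excl_tables, ignore_index=True).to_csv(out_dir / "exclusions.csv", index=False)
    tracksets_to_csv(tracksets, out_dir / "tracks.csv")
    return tracksets


def _arrest_rule(cfg: dict, tracksets: dict[str, TrackSet]) -> ArrestRule:
    arrest = cfg["arrest"]
    if "threshold" in arrest:
        thr = float(arrest["threshold"])
        return ArrestRule(thr, thr, 0.0)  # explicit threshold, provenance external
    static_label = arrest.get("static_group", "static")
    if static_label not in tracksets:
        raise ConfigError(f"arrest.static_group {static_label!r} not among groups "
                          f"{sorted(tracksets)}; or set arrest.threshold")
    return arrest_rule_from_static(tracksets[static_label])


def run_pipeline(config) -> dict:
    """Run the full pipeline from a config path or mapping.

    Returns a dict of artifact paths.  Any stage failure aborts with the
    stage name in the exception context.
    """
    cfg = validate_config(load_config(config) if not isinstance(config, dict)
                          else config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {"out_dir": str(out_dir)}
    stage = "acquire"
    try:
        tracksets = _acquire_tracksets(cfg, out_dir)
        artifacts["tracks"] = str(out_dir / "tracks.csv")
        log.info("groups: %s", {g: ts.n for g, ts in tracksets.items()})

        stage = "quantify"
        short_w = Window.short_term(float(cfg["windows"][0]))
        long_w = Window.long_term(float(cfg["windows"][1]))
        windows = [short_w, long_w]
        rule = _arrest_rule(cfg, tracksets)
        dir_rule = DirectionRule(flow_angle=float(cfg["flow_angle"]))

        per_cell_all, agg_all, speed_all, curve_rows, motility_rows = [], [], [], [], []
        curves = {}
        for label, ts in tracksets.items():
            per_cell, agg = summarize_group(ts, windows, rule, dir_rule)
            per_cell_all.append(per_cell)
            agg_all.append(agg)
            speed_all.append(ensemble_speed_timeseries(ts))
            curve = rms_displacement_curve(ts)
            curves[label] = curve
            curve_rows.append(curve.to_dataframe())
            for w_end in cfg["motility_windows"]:
                fit = motility_coefficient(curve, Window(0.0, float(w_end)))
                motility_rows.append({"group": label, "window_min": float(w_end),
                                      "slope_um_per_sqrt_min": fit.slope,
                                      "intercept_um": fit.intercept})
        per_cell_df = pd.concat(per_cell_all, ignore_index=True)
        per_cell_df.to_csv(out_dir / "summary_per_cell.csv", index=False)
        pd.concat(agg_all, ignore_index=True).to_csv(out_dir / "summary_groups.csv", index=False)
        pd.concat(speed_all, ignore_index=True).to_csv(out_dir / "speed_timeseries.csv", index=False)
        pd.concat(curve_rows, ignore_index=True).to_csv(out_dir / "rms_curves.csv", index=False)
        pd.DataFrame(motility_rows).to_csv(out_dir / "motility.csv", index=False)
        artifacts["summary_per_cell"] = str(out_dir / "summary_per_cell.csv")
        artifacts["arrest_rule"] = {"threshold": rule.threshold,
                                    "static_mean": rule.static_mean,
                                    "static_sd": rule.static_sd}

        stage = "stats"
        if len(tracksets) >= 2 and min(ts.n for ts in tracksets.values()) >= 2:
            stats_rows, reports = [], []
            for metric in cfg["stats"]["metrics"]:
                for w in windows:
                    sub = per_cell_df[per_cell_df["window"] == w.name]
                    groups = {g: s[metric].to_numpy() for g, s in sub.groupby("group")}
                    res = compare_groups(groups, metric=f"{metric}/{w.name}",
                                         transform=cfg["stats"]["transform"])
                    pw = res.pairwise.copy()
                    pw.insert(0, "window", w.name)
                    pw.insert(0, "metric", metric)
                    pw.insert(2, "anova_F", res.F)
                    pw.insert(3, "anova_p", res.anova_p)
                    stats_rows.append(pw)
                    reports.append(res.report())
            pd.concat(stats_rows, ignore_index=True).to_csv(out_dir / "stats.csv", index=False)
            (out_dir / "stats_report.txt").write_text("\n\n".join(reports) + "\n")
            artifacts["stats"] = str(out_dir / "stats.csv")

        stage = "plot"
        if cfg["plots"]:
            fig_dir = out_dir / "figures"
            fig_dir.mkdir(exist_ok=True)
            for label, ts in tracksets.items():
                safe = str(label).replace("/", "_")
                plot_tracks(ts, "raw", fig_dir / f"tracks_raw_{safe}.png")
                plot_tracks(ts, "compass", fig_dir / f"tracks_compass_{safe}.png")
            plot_curves(curves, "rms", fig_dir / "rms_displacement.png",
                        flow_onset_min=float(cfg["windows"][0]))
            speed_map = {d["group"].iloc[0]: d for d in speed_all}
            plot_curves(speed_map, "speed", fig_dir / "speed_timeseries.png")
            artifacts["figures"] = str(fig_dir)

        stage = "provenance"
        prov = {"config_hash": _config_hash(cfg), "seed": cfg.get("seed"),
                "flowtaxis_version": __version__, "numpy_version": np.__version__,
                "config": {k: v for k, v in cfg.items()}}
        (out_dir / "provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True, default=str) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
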