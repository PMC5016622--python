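"""End-to-end pipeline: build → trace → fit → simulate → validate.

Artifacts are plain CSV/JSON files in the configured output directory, plus
a manifest recording package version, seeds and input checksums so a run is
reproducible bit-for-bit from config + manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, architecture, canopy, fitting, light, synthetic
from .config import RunConfig

log = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_scene(cfg: RunConfig):
    """Construct the plant and the canopy grid from the run config."""
    if cfg.scene.structure_csv:
        table = architecture.read_structure_csv(cfg.scene.structure_csv)
    else:
        table = architecture.default_structure_table()
    spec = architecture.expand_layer_spec(table)
    plant = architecture.build_plant(
        spec, seed=cfg.scene.build_seed,
        phyllotaxis_jitter_deg=cfg.scene.phyllotaxis_jitter_deg)
    scene = architecture.build_canopy(plant, cfg.scene.rows, cfg.scene.cols,
                                      cfg.scene.spacing_m)
    return plant, scene


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured workflow; returns the artifact directory.

    Stages: build the scene; fit the capacity profile if curves are given
    (else use the packaged measured profile); simulate the day over the
    weather series (packaged synthetic day if none given); invert the chamber
    log into measured rates if given, and report goodness of fit.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for name in ("weather_csv", "curves_csv", "chamber_log_csv",
                 ):
        p = getattr(cfg, name)
        if p:
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(f"{name}: no such file {path}")
            inputs[name] = {"path": str(path), "sha256": _checksum(path)}
    scs = cfg.scene.structure_csv
    if scs and not Path(scs).exists():
        raise FileNotFoundError(f"structure_csv: no such file {scs}")

    plant, scene = build_scene(cfg)
    architecture.export_scene(scene, out / "scene.obj", fmt="obj")
    assignment = canopy.assign_layers(plant)

    # capacity profile: fitted from curves when provided, else the packaged
    # measured profile
    if cfg.curves_csv:
        curves = fitting.read_curves_csv(cfg.curves_csv)
        result = fitting.fit_layer_profile(
            curves, respiration_rule=cfg.fitting.respiration_rule)
        profile = result["profile"]
        (out / "trends.json").write_text(json.dumps(result["trends"], indent=2))
    else:
        profile = synthetic.capacity_profile()
    profile.to_csv(out / "capacity_profile.csv", index=False)
    layer_params = canopy.layer_params_from_profile(
        profile, n_layers=len(assignment.layers),
        respiration_rule=cfg.fitting.respiration_rule)

    if cfg.weather_csv:
        weather = pd.read_csv(cfg.weather_csv, parse_dates=["timestamp"])
    else:
        weather = synthetic.gen_weather_day()
    optics = light.OpticalProps(cfg.optics.reflectance, cfg.optics.transmittance)
    tcfg = light.TraceConfig(n_rays=cfg.trace.n_rays,
                             max_impacts=cfg.trace.max_impacts,
                             rng_seed=cfg.trace.seed,
                             n_batches=cfg.trace.n_batches)
    series = canopy.simulate_day(
        scene, weather, layer_params, assignment,
        site=cfg.site.model_dump() | {"utc_offset": cfg.site.utc_offset},
        ci_rule=cfg.ci_rule, ca_pa=cfg.ca_pa, trace_config=tcfg,
        optics=optics)
    sim_table = series.table.copy()

    stats = {}
    if cfg.chamber_log_csv:
        geom = canopy.ChamberGeometry(
            width=cfg.chamber.width, depth=cfg.chamber.depth,
            height=cfg.chamber.height,
            air_temperature_c=cfg.chamber.air_temperature_c,
            pressure_pa=cfg.chamber.pressure_pa,
            leak_rate=cfg.chamber.leak_rate)
        chamber_log = pd.read_csv(cfg.chamber_log_csv)
        measured = canopy.chamber_slope_to_rate(
            chamber_log, geom, subtract_leak=cfg.chamber.subtract_leak)
        sim_table["window"] = pd.to_datetime(sim_table["timestamp"]).dt.floor("30min")
        merged = sim_table.merge(measured, left_on="window",
                                 right_on="timestamp", suffixes=("", "_meas"))
        r2, rmse = canopy.goodness_of_fit(merged["measured"],
                                          merged["estimated"])
        stats = {"r_squared": r2, "rmse": rmse,
                 "n_windows": int(merged["measured"].notna().sum())}
        merged.drop(columns=["timestamp_meas", "window"]).to_csv(
            out / "flux_series.csv", index=False)
        (out / "stats.json").write_text(json.dumps(stats, indent=2))
    else:
        sim_table.to_csv(out / "flux_series.csv", index=False)

    manifest = {
        "package": "canophot",
        "version": __version__,
        "created": datetime.now().isoformat(timespec="seconds"),
        "config": cfg.model_dump(),
        "inputs": inputs,
        "seeds": {"build": cfg.scene.build_seed, "trace": cfg.trace.seed},
        "stats": stats,
        "n_leaves": len(plant.leaves),
        "total_leaf_area_m2": plant.total_leaf_area,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(artifact_dir) -> dict:
    """Summarise a pipeline run: JSON digest plus diagnostic plots.

    Produces `report.json` and, when matplotlib succeeds, `flux_series.png`
    (daily course of estimated vs measured rate) and `capacity_profile.png`
    (vertical distribution of Vcmax/Jmax).
    """
    out = Path(artifact_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    flux = pd.read_csv(out / "flux_series.csv", parse_dates=["timestamp"])
    profile = pd.read_csv(out / "capacity_profile.csv")
    summary = {
        "version": manifest["version"],
        "stats": manifest.get("stats", {}),
        "daily_mean_estimated": float(flux["estimated"].mean()),
        "daily_peak_estimated": float(flux["estimated"].max()),
        "n_steps": int(len(flux)),
        "profile_layers": profile["layer"].tolist(),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(flux["timestamp"], flux["estimated"], "o-", label="estimated")
        if "measured" in flux.columns:
            ax.plot(flux["timestamp"], flux["measured"], "s--", label="measured")
        ax.set_xlabel("time")
        ax.set_ylabel("whole-plant photosynthesis (μmol CO₂ s⁻¹)")
        ax.legend()
        fig.autofmt_xdate()
        fig.tight_layout()
        fig.savefig(out / "flux_series.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(profile["vlo"], profile["layer"],
                    xerr=profile.get("vlo_se"), fmt="o-", label="Vcmax")
        ax.errorbar(profile["jmo"], profile["layer"],
                    xerr=profile.get("jmo_se"), fmt="s-", label="Jmax")
        ax.set_xlabel("capacity (μmol m⁻² s⁻¹)")
        ax.set_ylabel("leaf layer")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "capacity_profile.png", dpi=120)
        plt.close(fig)
    except Exception as err:  # pragma: no cover - plotting is best-effort
        log.warning("plotting failed: %s", err)
    return summary
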