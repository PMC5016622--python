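"""Scaling leaf photosynthesis to the whole plant, and chamber validation.

Leaves are grouped acropetally (base to apex) into physiological layers of
four; each layer gets one parameter set and one mean absorbed irradiance, and
the plant rate is the area-weighted sum of the per-layer leaf rates.  A day
is simulated at half-hour steps by chaining solar position → ray trace →
layer means → FvCB.  The measured counterpart comes from a closed chamber:
whole-plant uptake equals the draw-down slope of the chamber CO2 mole
fraction times the molar content of the chamber air (ideal gas), with CO2
injection events masked out of the regression windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import constants as spc

from . import fvcb, light, solar
from .architecture import CanopyScene, PlantModel
from .fvcb import FvCBConstants, FvCBParams, LeafState, DEFAULT_CONSTANTS

__all__ = [
    "LayerAssignment",
    "ChamberGeometry",
    "CanopyFluxSeries",
    "assign_layers",
    "layer_params_from_profile",
    "plant_rate",
    "simulate_day",
    "chamber_slope_to_rate",
    "goodness_of_fit",
    "parse_ci_rule",
]

log = logging.getLogger(__name__)

R_GAS = spc.R  # J mol⁻¹ K⁻¹


@dataclass
class LayerAssignment:
    """Partition of a plant's leaves into physiological layers.

    ``layer_of`` maps leaf_id → 1-based layer number (counted acropetally);
    ``layer_area`` maps layer → total planform area [m²].
    """

    layer_of: dict
    layer_area: dict

    @property
    def layers(self) -> list:
        return sorted(self.layer_area)


def assign_layers(plant: PlantModel, leaves_per_layer: int = 4) -> LayerAssignment:
    """Group leaves bottom-to-top into layers of ``leaves_per_layer``.

    Leaves are ordered by node then stem; any remainder that cannot fill a
    whole layer joins the top layer.  Every leaf is assigned exactly once.
    """
    leaves = sorted(plant.leaves, key=lambda l: (l.node_index, l.stem_id))
    n = len(leaves)
    n_layers = max(n // leaves_per_layer, 1)
    layer_of, layer_area = {}, {}
    for i, leaf in enumerate(leaves):
        layer = min(i // leaves_per_layer + 1, n_layers)
        layer_of[leaf.leaf_id] = layer
        layer_area[layer] = layer_area.get(layer, 0.0) + leaf.planform_area
    return LayerAssignment(layer_of=layer_of, layer_area=layer_area)


def layer_params_from_profile(profile: pd.DataFrame, n_layers: int,
                              theta: float = 0.75,
                              respiration_rule: str = "table_coefficient") -> dict:
    """FvCB parameters for each of ``n_layers`` layers from a capacity profile.

    ``profile`` has columns layer, vlo, jmo (layer labels need not match the
    assignment's layer count: capacities are interpolated linearly over
    relative canopy depth, preserving the profile's top and bottom values).
    """
    prof = profile.sort_values("layer")
    labels = prof["layer"].to_numpy(float)
    lo, hi = labels.min(), labels.max()
    if n_layers == 1:
        coords = np.array([(lo + hi) / 2.0])
    else:
        coords = lo + (hi - lo) * (np.arange(n_layers) / (n_layers - 1))
    vlo = np.interp(coords, labels, prof["vlo"].to_numpy(float))
    jmo = np.interp(coords, labels, prof["jmo"].to_numpy(float))
    return {k + 1: FvCBParams(vl=float(vlo[k]), jm=float(jmo[k]), theta=theta,
                              respiration_rule=respiration_rule)
            for k in range(n_layers)}


def plant_rate(layer_irradiances, layer_params, layer_areas, ci: float,
               constants: FvCBConstants = DEFAULT_CONSTANTS):
    """Whole-plant net photosynthesis [μmol CO2 s⁻¹] plus per-layer terms.

    Σ_k A_l(params_k, I_k, ci) · area_k over equal-length layer vectors.
    Returns ``(total, per_layer_array)``.
    """
    irr = np.asarray(layer_irradiances, dtype=float)
    areas = np.asarray(layer_areas, dtype=float)
    if not (len(irr) == len(layer_params) == len(areas)):
        raise ValueError("layer vectors must have equal length")
    per_layer = np.array([
        fvcb.net_assimilation(p, LeafState(il=float(i), ci=ci), constants) * a
        for i, p, a in zip(irr, layer_params, areas)])
    return float(per_layer.sum()), per_layer


def parse_ci_rule(rule: str):
    """Parse an internal-CO2 rule: ``"ratio:0.7"`` (ci = ratio·ca) or
    ``"fixed:105"`` (ci constant, Pa).  Returns a callable ci(ca)."""
    kind, _, val = rule.partition(":")
    x = float(val)
    if kind == "ratio":
        if not 0 < x <= 1:
            raise ValueError("ci/ca ratio must lie in (0, 1]")
        return lambda ca: x * ca
    if kind == "fixed":
        if x < 0:
            raise ValueError("fixed ci must be non-negative")
        return lambda ca: x
    raise ValueError(f"unknown ci rule {rule!r}")


@dataclass
class CanopyFluxSeries:
    """Half-hourly whole-plant photosynthesis, estimated (and measured).

    ``table`` columns: timestamp, estimated, layer_<k>...; ``measured`` is
    merged in by :func:`goodness_of_fit` callers when available.
    """

    table: pd.DataFrame
    layer_columns: list

    def check_additivity(self, atol: float = 1e-9) -> bool:
        s = self.table[self.layer_columns].sum(axis=1)
        return bool(np.allclose(s, self.table["estimated"], atol=atol))


def simulate_day(scene, weather: pd.DataFrame, layer_params: dict,
                 assignment: LayerAssignment,
                 site: dict | None = None,
                 ci_rule: str = "ratio:0.7", ca_pa: float = 150.0,
                 trace_config: light.TraceConfig | None = None,
                 optics: light.OpticalProps = light.OpticalProps(),
                 constants: FvCBConstants = DEFAULT_CONSTANTS,
                 center_plant: int | None = None) -> CanopyFluxSeries:
    """Simulate whole-plant photosynthesis over a weather series.

    Per step: solar position at the step's timestamp → Monte Carlo trace →
    area-weighted layer irradiances on the centre plant → per-layer FvCB →
    plant rate.  ``ci_rule`` sets internal CO2 from the chamber/greenhouse
    CO2 setpoint ``ca_pa``.  Deterministic for a fixed trace seed (each step
    uses seed + step index so steps are independent but reproducible).
    """
    if site is None:
        site = {"latitude": 37.3, "longitude": 127.0, "utc_offset": 9.0,
                "north_offset": 0.0}
    cfg = trace_config or light.TraceConfig()
    ci_of = parse_ci_rule(ci_rule)
    ci = float(ci_of(ca_pa))
    if isinstance(scene, PlantModel):
        center = 0
    else:
        center = center_plant if center_plant is not None else scene.center_plant_id
    geom = light.flatten_scene(scene)
    layers = assignment.layers
    params = [layer_params[k] for k in layers]
    areas = [assignment.layer_area[k] for k in layers]

    rows = []
    for step, rec in enumerate(weather.itertuples(index=False)):
        ts = pd.Timestamp(rec.timestamp).to_pydatetime()
        ppfd = float(rec.ppfd)
        dfr = float(rec.diffuse_fraction)
        if ppfd > 0.0:
            sun = solar.solar_position(site["latitude"], site["longitude"],
                                       ts, site["utc_offset"],
                                       site.get("north_offset", 0.0))
            sky = light.SkyCondition(global_ppfd=ppfd, diffuse_fraction=dfr)
            sources = light.make_sources(sky, sun, geom.bounds,
                                         margin=cfg.emitter_margin)
            step_cfg = light.TraceConfig(
                n_rays=cfg.n_rays, max_impacts=cfg.max_impacts,
                rng_seed=cfg.rng_seed + step, n_batches=cfg.n_batches,
                emitter_margin=cfg.emitter_margin)
            imap = light.trace(geom, sources, optics, step_cfg)
            lm = light.layer_means(imap, assignment.layer_of, plant=center)
            irr = [float(lm.get(k, 0.0)) for k in layers]
        else:
            irr = [0.0] * len(layers)
        total, per_layer = plant_rate(irr, params, areas, ci, constants)
        row = {"timestamp": ts, "estimated": total}
        row.update({f"layer_{k}": float(v) for k, v in zip(layers, per_layer)})
        row.update({f"irradiance_{k}": float(v) for k, v in zip(layers, irr)})
        rows.append(row)
    table = pd.DataFrame(rows)
    return CanopyFluxSeries(table=table,
                            layer_columns=[f"layer_{k}" for k in layers])


@dataclass(frozen=True)
class ChamberGeometry:
    """Closed validation chamber: 1×1×2 m, stirred, at 25 °C.

    ``leak_rate`` is the chamber's CO2 leakage under the elevated-CO2
    experimental condition (0.2–0.3 μmol s⁻¹ measured; default 0.25).
    """

    width: float = 1.0
    depth: float = 1.0
    height: float = 2.0
    air_temperature_c: float = 25.0
    pressure_pa: float = 101325.0
    leak_rate: float = 0.25

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0 or self.height <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.leak_rate < 0:
            raise ValueError("leak rate must be non-negative")

    @property
    def volume(self) -> float:
        return self.width * self.depth * self.height

    @property
    def air_moles(self) -> float:
        """Molar content of the chamber air, n = PV/RT [mol]."""
        t_k = self.air_temperature_c + 273.15
        return self.pressure_pa * self.volume / (R_GAS * t_k)


def chamber_slope_to_rate(co2_log: pd.DataFrame,
                          geometry: ChamberGeometry = ChamberGeometry(),
                          window: str = "30min",
                          injection_jump_pa: float = 2.0,
                          guard_samples: int = 12,
                          min_samples: int = 10,
                          subtract_leak: bool = False) -> pd.DataFrame:
    """Invert a chamber CO2 log (columns timestamp, co2_pa) to uptake rates.

    Within each ``window``, the least-squares slope of CO2 mole fraction vs
    time, times the chamber's molar air content, gives the CO2 removal rate
    in μmol s⁻¹.  Injection events — a rise exceeding ``injection_jump_pa``
    between consecutive samples — are masked from the jump until the decline
    resumes, and the slope is fitted separately on each contiguous declining
    segment (an injection shifts the CO2 level, so a single regression across
    the jump would see a spurious positive slope); segment slopes are
    combined weighted by sample count.  Windows with fewer than
    ``min_samples`` unmasked samples yield NaN (logged).  With
    ``subtract_leak`` the chamber leak rate is removed so the result is plant
    uptake alone; otherwise the raw draw-down rate (uptake + leak) is
    reported.
    """
    df = co2_log.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp").reset_index(drop=True)
    co2 = df["co2_pa"].to_numpy(float)
    # injection masking: from each detected jump, mask while CO2 still rises,
    # then hold the mask for a guard period — the valve's exponential tail
    # can balance uptake and fake a zero slope long after the jump
    diff = np.diff(co2, prepend=co2[0])
    mask = np.zeros(len(co2), dtype=bool)
    in_injection = False
    guard = 0
    for i in range(1, len(co2)):
        if diff[i] > injection_jump_pa:
            in_injection = True
        elif in_injection and diff[i] <= 0.0:
            in_injection = False
            guard = guard_samples
        if in_injection:
            mask[i] = True
        elif guard > 0:
            mask[i] = True
            guard -= 1
    df["masked"] = mask

    t0 = df["timestamp"].iloc[0]
    df["t_s"] = (df["timestamp"] - t0).dt.total_seconds()
    x_ppm = co2 / geometry.pressure_pa * 1e6  # μmol CO2 per mol air
    df["x_ppm"] = x_ppm
    n_air = geometry.air_moles

    out = []
    for wstart, g in df.groupby(df["timestamp"].dt.floor(window)):
        keep = (~g["masked"]).to_numpy()
        if keep.sum() < min_samples:
            log.warning("chamber window %s: only %d unmasked samples",
                        wstart, int(keep.sum()))
            out.append({"timestamp": wstart, "measured": np.nan,
                        "n_samples": int(keep.sum())})
            continue
        t = g["t_s"].to_numpy()
        x = g["x_ppm"].to_numpy()
        # contiguous unmasked segments
        edges = np.flatnonzero(np.diff(keep.astype(int)))
        bounds = np.concatenate([[0], edges + 1, [len(keep)]])
        slopes, weights = [], []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if not keep[a] or b - a < 3:
                continue
            slopes.append(np.polyfit(t[a:b], x[a:b], 1)[0])
            weights.append(b - a)
        if not slopes:
            out.append({"timestamp": wstart, "measured": np.nan,
                        "n_samples": int(keep.sum())})
            continue
        slope = float(np.average(slopes, weights=weights))
        rate = -slope * n_air  # μmol s⁻¹ removed from the chamber air
        if subtract_leak:
            rate -= geometry.leak_rate
        out.append({"timestamp": wstart, "measured": rate,
                    "n_samples": int(keep.sum())})
    return pd.DataFrame(out)


def goodness_of_fit(measured, estimated) -> tuple[float, float]:
    """(R², RMSE) of estimated against measured; NaN pairs are dropped.

    R² = 1 − SS_res/SS_tot with measured as the reference; RMSE in the
    series' own units.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(m) & np.isfinite(e)
    m, e = m[ok], e[ok]
    if len(m) == 0:
        return np.nan, np.nan
    ss_res = float(np.sum((m - e) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    rmse = float(np.sqrt(np.mean((m - e) ** 2)))
    return r2, rmse
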