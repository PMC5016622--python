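"""Per-leaf light interception by Monte Carlo ray tracing.

The sky is split into a direct beam (parallel rays along the sun vector) and
an isotropic diffuse component; both are emitted from a horizontal plane
above the scene whose horizontal photon flux equals the measured global PPFD,
so per-leaf scores are directly in μmol m⁻² s⁻¹.  Leaves scatter with a
bi-Lambertian model (identical reflectance ρ and transmittance τ on both
sides); stems are opaque black.  See :mod:`canophot._tracing_kernels` for the
energy-accounting contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from . import _tracing_kernels as _k
from .architecture import CanopyScene, PlantModel, TriMesh
from .solar import SunPosition, sun_direction

__all__ = [
    "OpticalProps",
    "SkyCondition",
    "TraceConfig",
    "SceneGeometry",
    "InterceptionMap",
    "flatten_scene",
    "make_sources",
    "trace",
    "layer_means",
    "beer_lambert_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OpticalProps:
    """Leaf optical properties (same on both blade sides).

    Defaults are integrating-sphere values for greenhouse paprika leaves:
    reflectance 0.10, transmittance 0.07, hence absorptance 0.83.
    """

    reflectance: float = 0.10
    transmittance: float = 0.07

    def __post_init__(self) -> None:
        if self.reflectance < 0 or self.transmittance < 0:
            raise ValueError("reflectance and transmittance must be >= 0")
        if self.reflectance + self.transmittance > 1.0:
            raise ValueError("reflectance + transmittance must not exceed 1")

    @property
    def absorptance(self) -> float:
        return 1.0 - self.reflectance - self.transmittance


@dataclass(frozen=True)
class SkyCondition:
    """Global horizontal PPFD [μmol m⁻² s⁻¹] and its diffuse fraction."""

    global_ppfd: float
    diffuse_fraction: float
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        if self.global_ppfd < 0:
            raise ValueError("global_ppfd must be non-negative")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TraceConfig:
    """Monte Carlo budget and reproducibility knobs.

    ``n_rays`` defaults to 10⁶ (desk scale; scales linearly to larger
    budgets), ``max_impacts`` bounds the scattering chain, ``n_batches``
    controls the batch-mean standard-error estimate.
    """

    n_rays: int = 1_000_000
    max_impacts: int = 10
    rng_seed: int = 0
    n_batches: int = 16
    emitter_margin: float | None = None  # metres; default derived from scene

    def __post_init__(self) -> None:
        if self.n_rays < 1 or self.max_impacts < 1 or self.n_batches < 1:
            raise ValueError("n_rays, max_impacts and n_batches must be >= 1")


@dataclass
class SceneGeometry:
    """Flattened triangle soup with per-triangle leaf tags.

    ``tri_leaf[i]`` is the row index into ``leaf_table`` of the leaf owning
    triangle i, or −1 for opaque surfaces (stems).  ``leaf_table`` has columns
    plant, leaf_id, stem, node, area_m2.
    """

    tris: np.ndarray           # (m, 3, 3) float64
    tri_leaf: np.ndarray       # (m,) int64
    leaf_table: pd.DataFrame
    n_degenerate: int = 0

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if len(self.tris) == 0:
            z = np.zeros(3)
            return z, z + 1.0
        flat = self.tris.reshape(-1, 3)
        return flat.min(axis=0), flat.max(axis=0)


def _mesh_tris(mesh: TriMesh) -> np.ndarray:
    return mesh.vertices[mesh.faces]


def flatten_scene(scene, include_stems: bool = True) -> SceneGeometry:
    """Flatten a :class:`CanopyScene` (or single :class:`PlantModel`) for
    tracing.  Degenerate (near-zero-area) triangles are dropped and counted.
    """
    if isinstance(scene, PlantModel):
        plants = [scene]
    elif isinstance(scene, CanopyScene):
        plants = scene.plants
    else:
        raise TypeError("scene must be a PlantModel or CanopyScene")
    tri_blocks, tag_blocks, rows = [], [], []
    leaf_row = 0
    for pid, plant in enumerate(plants):
        if include_stems:
            for stem in plant.stems:
                t = _mesh_tris(stem)
                tri_blocks.append(t)
                tag_blocks.append(np.full(len(t), -1, dtype=np.int64))
        for leaf in plant.leaves:
            t = _mesh_tris(leaf.mesh)
            tri_blocks.append(t)
            tag_blocks.append(np.full(len(t), leaf_row, dtype=np.int64))
            rows.append({"plant": pid, "leaf_id": leaf.leaf_id,
                         "stem": leaf.stem_id, "node": leaf.node_index,
                         "area_m2": leaf.planform_area})
            leaf_row += 1
    if tri_blocks:
        tris = np.ascontiguousarray(np.vstack(tri_blocks), dtype=np.float64)
        tags = np.concatenate(tag_blocks)
    else:
        tris = np.zeros((0, 3, 3))
        tags = np.zeros(0, dtype=np.int64)
    # drop degenerate triangles
    if len(tris):
        areas = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
        scale = max(float(areas.max()), 1e-30)
        keep = areas > 1e-12 * scale
        n_deg = int((~keep).sum())
        if n_deg:
            log.warning("dropped %d degenerate triangles", n_deg)
        tris, tags = tris[keep], tags[keep]
    else:
        n_deg = 0
    table = pd.DataFrame(rows, columns=["plant", "leaf_id", "stem", "node",
                                        "area_m2"])
    return SceneGeometry(tris=tris, tri_leaf=tags, leaf_table=table,
                         n_degenerate=n_deg)


def make_sources(sky: SkyCondition, sun: SunPosition | None,
                 bounds: tuple, margin: float | None = None,
                 beam_zenith_cutoff: float = 85.0) -> list[dict]:
    """Build the emitter set for a sky condition over a scene AABB.

    Returns a list of emitter dicts (kind ``"beam"``/``"diffuse"``) whose
    summed horizontal-plane flux equals ``sky.global_ppfd`` per unit emitter
    area by construction.  The direct emitter is dropped when the diffuse
    fraction is 1 or the sun is below the horizon.  Within
    ``beam_zenith_cutoff`` degrees of the horizon the direct share is folded
    into the diffuse sky: a horizontal-flux convention would imply an
    unbounded beam radiance as cos(zenith) → 0, and real near-horizon global
    light is diffuse-dominated anyway.

    The beam emitter is the scene footprint translated up-sun (plus a small
    margin), so slanted rays cover the scene without inflating the emitter
    area — important for Monte Carlo efficiency at low sun.
    """
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    height = max(hi[2] - lo[2], 0.1)
    z_emit = hi[2] + 0.05 * height + 0.01
    sources: list[dict] = []
    direct = sky.global_ppfd * (1.0 - sky.diffuse_fraction)
    diffuse = sky.global_ppfd * sky.diffuse_fraction
    beam_up = (sun is not None and sun.above_horizon
               and sun.zenith < beam_zenith_cutoff)
    if direct > 0.0 and not beam_up:
        diffuse += direct
        direct = 0.0
    if direct > 0.0 and beam_up:
        d = np.asarray(sun_direction(sun))
        d = d / np.linalg.norm(d)
        # horizontal displacement of a ray between emitter and ground level
        drop = z_emit - lo[2]
        shift_x = d[0] / abs(d[2]) * drop
        shift_y = d[1] / abs(d[2]) * drop
        m = (margin if margin is not None else 0.05 * max(hi[0] - lo[0],
                                                          hi[1] - lo[1], 0.2))
        rect = (lo[0] - m - max(shift_x, 0.0), hi[0] + m - min(shift_x, 0.0),
                lo[1] - m - max(shift_y, 0.0), hi[1] + m - min(shift_y, 0.0))
        sources.append({"kind": "beam", "rect": rect, "z": float(z_emit),
                        "direction": tuple(d),
                        "flux_per_area": direct})
    if diffuse > 0.0:
        m = (margin if margin is not None else
             1.0 * (z_emit - lo[2]) + 0.05 * max(hi[0] - lo[0], hi[1] - lo[1], 0.2))
        rect = (lo[0] - m, hi[0] + m, lo[1] - m, hi[1] + m)
        sources.append({"kind": "diffuse", "rect": rect, "z": float(z_emit),
                        "direction": (0.0, 0.0, -1.0),
                        "flux_per_area": diffuse})
    return sources


@dataclass
class InterceptionMap:
    """Per-leaf absorbed light plus whole-trace energy bookkeeping.

    ``per_leaf`` columns: plant, leaf_id, stem, node, area_m2,
    absorbed_umol_s (flux), absorbed_umol_m2_s (irradiance = flux/area),
    mc_se (Monte Carlo SE of the irradiance).  Totals are in μmol s⁻¹.
    """

    per_leaf: pd.DataFrame
    emitted_total: float
    escaped_total: float
    truncated_total: float
    absorbed_other_total: float

    @property
    def absorbed_total(self) -> float:
        return float(self.per_leaf["absorbed_umol_s"].sum())

    @property
    def balance_residual(self) -> float:
        """emitted − (absorbed + escaped + truncated + opaque) — ≈0 always."""
        return self.emitted_total - (self.absorbed_total + self.escaped_total
                                     + self.truncated_total
                                     + self.absorbed_other_total)

    def to_csv(self, path, layer_of: dict | None = None) -> None:
        df = self.per_leaf.copy()
        df["layer"] = (df["leaf_id"].map(layer_of) if layer_of is not None
                       else pd.NA)
        df[["leaf_id", "stem", "node", "layer", "area_m2",
            "absorbed_umol_m2_s", "mc_se"]].to_csv(path, index=False)


def _grid_dims(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    flat = tris.reshape(-1, 3)
    lo = flat.min(axis=0)
    hi = flat.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    pad = 1e-6 + 1e-9 * span.max()
    lo, hi = lo - pad, hi + pad
    span = hi - lo
    # ~2 triangles per occupied cell on average, axes scaled by extent
    target = max(int(round((len(tris) / 2.0) ** (1.0 / 3.0))), 1)
    rel = span / span.max()
    ndiv = np.maximum((target * 4 * rel).astype(np.int64), 1)
    ndiv = np.minimum(ndiv, 128)
    cell = span / ndiv
    return lo, hi, cell, ndiv


def trace(scene, sources: list[dict], optics: OpticalProps = OpticalProps(),
          config: TraceConfig = TraceConfig()) -> InterceptionMap:
    """Trace all emitters through the scene and score per-leaf absorption.

    ``scene`` may be a :class:`SceneGeometry` or anything accepted by
    :func:`flatten_scene`.  The ray budget is split across emitters in
    proportion to their emitted flux.  Reproducible for a fixed
    ``config.rng_seed``; results are independent of batch partitioning.
    """
    geom = scene if isinstance(scene, SceneGeometry) else flatten_scene(scene)
    n_leaves = len(geom.leaf_table)
    nb = config.n_batches
    absorbed = np.zeros((nb, max(n_leaves, 1)))
    escaped = np.zeros(nb)
    truncated = np.zeros(nb)
    other = np.zeros(nb)
    emitted = 0.0

    if len(geom.tris):
        gmin, gmax, cell, ndiv = _grid_dims(geom.tris)
        starts, items = _k.build_grid(geom.tris, gmin, cell, ndiv)
        eps_t = 1e-9 * float(np.linalg.norm(gmax - gmin))
        normals = np.cross(geom.tris[:, 1] - geom.tris[:, 0],
                           geom.tris[:, 2] - geom.tris[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.ascontiguousarray(normals)
    else:
        gmin = np.zeros(3)
        gmax = np.ones(3)
        cell = np.ones(3)
        ndiv = np.ones(3, np.int64)
        starts = np.zeros(2, np.int64)
        items = np.zeros(0, np.int64)
        eps_t = 1e-9
        normals = np.zeros((0, 3))

    fluxes = []
    for src in sources:
        rect = src["rect"]
        area = (rect[1] - rect[0]) * (rect[3] - rect[2])
        fluxes.append(src["flux_per_area"] * area)
    total_flux = sum(fluxes)
    if total_flux <= 0.0 or not sources:
        imap_df = geom.leaf_table.copy()
        imap_df["absorbed_umol_s"] = 0.0
        imap_df["absorbed_umol_m2_s"] = 0.0
        imap_df["mc_se"] = 0.0
        return InterceptionMap(imap_df, 0.0, 0.0, 0.0, 0.0)

    ray_offset = 0
    for src, flux in zip(sources, fluxes):
        n_rays = max(int(round(config.n_rays * flux / total_flux)), 1)
        energy = flux / n_rays
        emitted += flux
        kind = 0 if src["kind"] == "beam" else 1
        rect = np.asarray(src["rect"], dtype=np.float64)
        beam = np.asarray(src["direction"], dtype=np.float64)
        _k.trace_emitter(geom.tris, geom.tri_leaf, normals,
                         gmin, gmax, cell, ndiv, starts, items,
                         kind, rect, float(src["z"]), beam, energy,
                         optics.reflectance, optics.transmittance,
                         config.max_impacts,
                         config.rng_seed, ray_offset, n_rays, nb,
                         absorbed, escaped, truncated, other, eps_t)
        ray_offset += n_rays

    flux_leaf = absorbed[:, :n_leaves].sum(axis=0)
    # batch-mean standard error of the flux (each batch is an unbiased
    # estimator of the total when scaled by n_batches)
    if nb > 1 and n_leaves:
        se_flux = absorbed[:, :n_leaves].std(axis=0, ddof=1) * math.sqrt(nb)
    else:
        se_flux = np.zeros(n_leaves)
    df = geom.leaf_table.copy()
    df["absorbed_umol_s"] = flux_leaf
    area = df["area_m2"].to_numpy()
    df["absorbed_umol_m2_s"] = np.where(area > 0, flux_leaf / area, 0.0)
    df["mc_se"] = np.where(area > 0, se_flux / area, 0.0)
    return InterceptionMap(df, float(emitted), float(escaped.sum()),
                           float(truncated.sum()), float(other.sum()))


def layer_means(imap: InterceptionMap, layer_of: dict,
                plant: int | None = None) -> pd.Series:
    """Area-weighted mean absorbed irradiance per canopy layer.

    ``layer_of`` maps leaf_id → layer number (see
    :func:`canophot.canopy.assign_layers`); restrict to one plant of a
    multi-plant scene with ``plant=`` (detectors sit on the centre plant).
    """
    df = imap.per_leaf
    if plant is not None:
        df = df[df["plant"] == plant]
    df = df.assign(layer=df["leaf_id"].map(layer_of)).dropna(subset=["layer"])
    grp = df.groupby("layer")
    out = grp.apply(
        lambda g: g["absorbed_umol_s"].sum() / g["area_m2"].sum(),
        include_groups=False)
    out.name = "absorbed_umol_m2_s"
    return out


def beer_lambert_profile(i0: float, k: float, cumulative_lai) -> np.ndarray:
    """Reference exponential extinction I0·exp(−k·LAI) (used in tests as the
    turbid-medium limit of the ray tracer)."""
    return i0 * np.exp(-k * np.asarray(cumulative_lai, dtype=float))
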