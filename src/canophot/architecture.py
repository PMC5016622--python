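"""Parametric 3D reconstruction of a two-stem, V-trellised sweet-pepper plant.

A plant is built from a per-node structural table (leaf area, petiole length,
blade droop angle, internode length, stem radius).  Greenhouse paprika is
pruned to two primary stems trellised into a "V"; each stem carries 15 nodes
with one leaf per node.  Structural tables are typically measured on odd
nodes only, so :func:`expand_layer_spec` fills even nodes by linear
interpolation.

Geometry conventions: right-handed, z-up, ground at z = 0, rows along x, all
lengths in metres internally (cm/mm accepted at the CSV boundary).  The two
stems lean ±30° from vertical within the row (x–z) plane; leaves alternate
180° in azimuth node-to-node with a small seeded jitter.  Leaf blades are
flat cordate polygons scaled to the target planform area and pitched below
the horizontal by the measured droop angle at the petiole tip.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LayerStructSpec",
    "TriMesh",
    "LeafGeom",
    "PlantModel",
    "CanopyScene",
    "leaf_area_from_dims",
    "read_structure_csv",
    "default_structure_table",
    "expand_layer_spec",
    "cordate_template",
    "build_plant",
    "build_canopy",
    "export_scene",
    "load_scene_mesh",
]

N_NODES = 15
STEM_LEAN_DEG = 30.0

STRUCTURE_COLUMNS = ["layer", "leaf_area_cm2", "petiole_cm", "droop_deg",
                     "n_leaves", "stem_radius_mm", "internode_cm"]


# --------------------------------------------------------------------------
# Structural specification


@dataclass(frozen=True)
class LayerStructSpec:
    """Structural measurements for one node layer (boundary units: cm/mm/°)."""

    layer_index: int
    leaf_area: float        # cm² per leaf
    petiole_length: float   # cm
    droop_angle: float      # degrees below horizontal
    n_leaves: int           # leaves per layer per plant
    stem_radius: float      # mm
    internode_length: float  # cm

    def __post_init__(self) -> None:
        if min(self.leaf_area, self.petiole_length, self.stem_radius,
               self.internode_length) <= 0:
            raise ValueError("lengths and areas must be positive")
        if not 0.0 <= self.droop_angle <= 90.0:
            raise ValueError("droop angle must lie in [0, 90] degrees")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be at least 1")


def leaf_area_from_dims(length_cm: float, width_cm: float) -> float:
    """Planform leaf area from blade length and width (cm²).

    Empirical allometry for sweet pepper: LA = 0.6034 L·W + 0.0732.
    """
    if length_cm < 0 or width_cm < 0:
        raise ValueError("leaf dimensions must be non-negative")
    return 0.6034 * length_cm * width_cm + 0.0732


def read_structure_csv(path) -> pd.DataFrame:
    """Read a structural table CSV (columns: layer, leaf_area_cm2, petiole_cm,
    droop_deg, n_leaves, stem_radius_mm, internode_cm), sorted by layer."""
    df = pd.read_csv(path)
    missing = set(STRUCTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"structure CSV missing columns: {sorted(missing)}")
    df = df[STRUCTURE_COLUMNS].sort_values("layer").reset_index(drop=True)
    if df["layer"].duplicated().any():
        raise ValueError("duplicate layer indices in structure CSV")
    return df


def default_structure_table() -> pd.DataFrame:
    """The packaged greenhouse-paprika structural table (odd nodes 1..15)."""
    text = resources.files("canophot.data").joinpath(
        "paprika_layer_structure.csv").read_text()
    return read_structure_csv(io.StringIO(text))


def expand_layer_spec(odd_layer_table: pd.DataFrame,
                      n_nodes: int = N_NODES) -> list[LayerStructSpec]:
    """Fill all nodes 1..n_nodes from a table of (typically odd) measured nodes.

    Measured nodes are reproduced exactly; unmeasured ones are linearly
    interpolated between bracketing measurements.  The table must cover the
    first and last node.  ``n_leaves`` is interpolated then rounded.
    """
    df = read_structure_csv(io.StringIO(odd_layer_table.to_csv(index=False))) \
        if not isinstance(odd_layer_table, pd.DataFrame) else \
        odd_layer_table[STRUCTURE_COLUMNS].sort_values("layer").reset_index(drop=True)
    layers = df["layer"].to_numpy(dtype=float)
    if layers[0] > 1 or layers[-1] < n_nodes:
        raise ValueError(
            f"structure table must cover nodes 1 and {n_nodes}; "
            f"got range {int(layers[0])}..{int(layers[-1])}")
    nodes = np.arange(1, n_nodes + 1, dtype=float)
    interp = {c: np.interp(nodes, layers, df[c].to_numpy(dtype=float))
              for c in STRUCTURE_COLUMNS[1:]}
    return [LayerStructSpec(
        layer_index=int(k),
        leaf_area=float(interp["leaf_area_cm2"][i]),
        petiole_length=float(interp["petiole_cm"][i]),
        droop_angle=float(interp["droop_deg"][i]),
        n_leaves=int(round(interp["n_leaves"][i])),
        stem_radius=float(interp["stem_radius_mm"][i]),
        internode_length=float(interp["internode_cm"][i]),
    ) for i, k in enumerate(nodes)]


# --------------------------------------------------------------------------
# Meshes


@dataclass
class TriMesh:
    """Triangle soup: (n,3) float64 vertices in metres, (m,3) int32 faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int32)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices must be finite")

    @property
    def area(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        return TriMesh(v + np.asarray(translation, dtype=float), self.faces.copy())


@dataclass
class LeafGeom:
    """One leaf blade: mesh plus its node/stem tags and placement angles."""

    leaf_id: int
    node_index: int
    stem_id: int
    mesh: TriMesh
    planform_area: float  # m²
    azimuth: float        # degrees
    droop: float          # degrees


@dataclass
class PlantModel:
    """Two-stem plant: stem meshes plus an ordered list of leaves."""

    stems: list
    leaves: list
    origin: tuple = (0.0, 0.0, 0.0)
    height: float = 0.0

    def __post_init__(self) -> None:
        if len(self.stems) != 2:
            raise ValueError("a plant must have exactly 2 stems")

    @property
    def total_leaf_area(self) -> float:
        return sum(l.planform_area for l in self.leaves)

    def translated(self, offset) -> "PlantModel":
        off = np.asarray(offset, dtype=float)
        return PlantModel(
            stems=[s.transformed(translation=off) for s in self.stems],
            leaves=[LeafGeom(l.leaf_id, l.node_index, l.stem_id,
                             l.mesh.transformed(translation=off),
                             l.planform_area, l.azimuth, l.droop)
                    for l in self.leaves],
            origin=tuple(np.asarray(self.origin) + off),
            height=self.height)


@dataclass
class CanopyScene:
    """A grid of placed plants; detectors live on the centre plant."""

    plants: list
    spacing: float
    rows: int
    cols: int
    center_plant_id: int

    def __post_init__(self) -> None:
        if len(self.plants) != self.rows * self.cols:
            raise ValueError("plant count must equal rows*cols")


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_axis(axis, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)


def cordate_template(n_perimeter: int = 24, aspect: float = 1.4) -> TriMesh:
    """Flat cordate (heart-shaped) leaf-blade polygon of unit area.

    Midrib along +x from the attachment point at the origin, blade in the
    x–y plane, fan-triangulated from the centroid (~``n_perimeter``
    triangles).  ``aspect`` is the length:width ratio of the outline.
    """
    t = np.linspace(0.0, 2.0 * math.pi, n_perimeter, endpoint=False)
    # Cardioid-like outline with a basal notch, parameterised about the base.
    r = 1.0 - 0.55 * np.cos(t)
    x = r * np.cos(t)
    y = r * np.sin(t)
    x = (x - x.min())  # attachment (leaf base) at x = 0
    pts = np.column_stack([x, y * (x.max() / (aspect * (y.max() - y.min())))])
    centroid = pts.mean(axis=0)
    verts2 = np.vstack([centroid, pts])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % n_perimeter]
                      for i in range(n_perimeter)], dtype=np.int32)
    verts = np.column_stack([verts2, np.zeros(len(verts2))])
    mesh = TriMesh(verts, faces)
    s = 1.0 / math.sqrt(mesh.area)  # normalise to unit area
    mesh.vertices[:, :2] *= s
    # shift so the basal tip sits exactly at the origin
    mesh.vertices[:, 0] -= mesh.vertices[:, 0].min()
    return mesh


def _stem_segment(p0, p1, radius: float, n_sides: int = 8) -> TriMesh:
    """Closed prism of circular cross-section between two node points."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    ang = np.linspace(0, 2 * math.pi, n_sides, endpoint=False)
    ring = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))
    verts = np.vstack([p0 + ring, p1 + ring])
    faces = []
    for i in range(n_sides):
        j = (i + 1) % n_sides
        faces.append([i, j, n_sides + i])
        faces.append([j, n_sides + j, n_sides + i])
    return TriMesh(verts, np.array(faces, dtype=np.int32))


def _merge(meshes: list) -> TriMesh:
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return TriMesh(np.vstack(verts), np.vstack(faces))


def build_plant(spec: list, seed: int = 0,
                phyllotaxis_jitter_deg: float = 10.0,
                leaf_template: TriMesh | None = None,
                stem_lean_deg: float = STEM_LEAN_DEG) -> PlantModel:
    """Build a two-stem plant from a per-node structural spec.

    ``spec`` is the output of :func:`expand_layer_spec` (15 nodes).  Each stem
    carries one leaf per node; leaf azimuths alternate 180° node-to-node with
    a seeded Gaussian jitter (σ = ``phyllotaxis_jitter_deg``).  Deterministic
    for a fixed seed.  Each blade is scaled so its mesh planform area matches
    the spec area exactly (well within the 1% contract).
    """
    if len(spec) != N_NODES:
        raise ValueError(f"spec must cover exactly {N_NODES} nodes")
    if any(s.leaf_area <= 0 for s in spec):
        raise ValueError("leaf areas must be positive")
    template = leaf_template if leaf_template is not None else cordate_template()
    t_area = template.area
    if abs(t_area - 1.0) > 1e-6:
        raise ValueError("leaf template must have unit area")

    rng = np.random.default_rng(seed)
    stems, leaves = [], []
    leaf_id = 0
    height = 0.0
    for stem_id in (0, 1):
        lean = stem_lean_deg if stem_id == 0 else -stem_lean_deg
        d = np.array([math.sin(math.radians(lean)), 0.0,
                      math.cos(math.radians(lean))])
        base = np.array([0.02 if stem_id == 0 else -0.02, 0.0, 0.0])
        node_pts = [base.copy()]
        for s in spec:
            node_pts.append(node_pts[-1] + d * (s.internode_length / 100.0))
        segs = [_stem_segment(node_pts[i], node_pts[i + 1],
                              spec[i].stem_radius / 1000.0)
                for i in range(N_NODES)]
        stems.append(_merge(segs))
        height = max(height, float(node_pts[-1][2]))

        base_az = 90.0 if stem_id == 0 else 270.0
        for i, s in enumerate(spec):
            node = node_pts[i + 1]
            az = (base_az + 180.0 * i + rng.normal(0.0, phyllotaxis_jitter_deg)) % 360.0
            area_m2 = s.leaf_area * 1e-4
            scale = math.sqrt(area_m2)
            blade = TriMesh(template.vertices * scale, template.faces)
            # pitch blade down by the droop angle, then swing to azimuth;
            # azimuth measured clockwise from +y (north)
            r = _rot_z(90.0 - az) @ _rot_axis([0, 1, 0], s.droop_angle)
            petiole_dir = _rot_z(90.0 - az) @ np.array([1.0, 0.0, 0.0])
            tip = node + petiole_dir * (s.petiole_length / 100.0)
            mesh = blade.transformed(rotation=r, translation=tip)
            leaves.append(LeafGeom(leaf_id, s.layer_index, stem_id, mesh,
                                   planform_area=area_m2, azimuth=az,
                                   droop=s.droop_angle))
            leaf_id += 1
    leaves.sort(key=lambda l: (l.node_index, l.stem_id))
    for new_id, l in enumerate(leaves):
        l.leaf_id = new_id
    return PlantModel(stems=stems, leaves=leaves, height=height)


def build_canopy(plant: PlantModel, rows: int, cols: int,
                 spacing_m: float = 0.8) -> CanopyScene:
    """Replicate a plant onto a rows×cols grid (rows along x).

    The centre plant (defined for odd rows and cols, else the grid cell
    nearest the centroid) is the one detectors report on.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be at least 1")
    plants = []
    for r in range(rows):
        for c in range(cols):
            off = ((r - (rows - 1) / 2.0) * spacing_m,
                   (c - (cols - 1) / 2.0) * spacing_m, 0.0)
            plants.append(plant.translated(off))
    center = (rows // 2) * cols + cols // 2
    return CanopyScene(plants=plants, spacing=spacing_m, rows=rows,
                       cols=cols, center_plant_id=center)


# --------------------------------------------------------------------------
# Mesh I/O


def _scene_groups(scene: CanopyScene):
    """Yield (group_name, mesh) pairs; leaf groups only for the centre plant
    carry detector semantics but every leaf is named."""
    for pid, plant in enumerate(scene.plants):
        for sid, stem in enumerate(plant.stems):
            yield f"stem_{pid}_{sid}", stem
        for l in plant.leaves:
            yield f"leaf_{pid}_{l.stem_id}_{l.node_index}_{l.leaf_id}", l.mesh


def export_scene(scene: CanopyScene, path, fmt: str = "obj") -> Path:
    """Write the scene as a Wavefront OBJ (named groups) or binary PLY."""
    path = Path(path)
    if fmt == "obj":
        with open(path, "w") as fh:
            fh.write("# canophot canopy scene\n")
            offset = 1
            for name, mesh in _scene_groups(scene):
                fh.write(f"g {name}\n")
                for v in mesh.vertices:
                    fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                for f in mesh.faces:
                    fh.write(f"f {f[0]+offset} {f[1]+offset} {f[2]+offset}\n")
                offset += len(mesh.vertices)
    elif fmt == "ply":
        import trimesh as _tm
        merged = _merge([m for _, m in _scene_groups(scene)])
        _tm.Trimesh(vertices=merged.vertices, faces=merged.faces,
                    process=False).export(path, file_type="ply")
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    return path


def load_scene_mesh(path) -> dict:
    """Re-import an exported scene as a dict of group name → TriMesh.

    OBJ files are parsed directly (preserving the named ``g`` groups the
    exporter writes); other formats go through trimesh as a single group.
    """
    path = Path(path)
    if path.suffix.lower() != ".obj":
        import trimesh as _tm
        loaded = _tm.load(str(path), process=False, maintain_order=True)
        return {"scene": TriMesh(np.asarray(loaded.vertices),
                                 np.asarray(loaded.faces))}
    verts: list = []
    groups: dict = {}
    current = "default"
    for line in path.read_text().splitlines():
        if line.startswith("v "):
            verts.append([float(x) for x in line.split()[1:4]])
        elif line.startswith("g "):
            current = line[2:].strip()
        elif line.startswith("f "):
            idx = [int(tok.split("/")[0]) - 1 for tok in line.split()[1:4]]
            groups.setdefault(current, []).append(idx)
    vertices = np.asarray(verts, dtype=float)
    out = {}
    for name, faces in groups.items():
        faces = np.asarray(faces, dtype=np.int64)
        used = np.unique(faces)
        remap = {int(g): l for l, g in enumerate(used)}
        local = np.vectorize(remap.get)(faces)
        out[name] = TriMesh(vertices[used], local)
    return out
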