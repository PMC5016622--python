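"""Shared fixtures: the reference plant, flat-leaf toy scenes, small trace
budgets.  Everything is generated programmatically; no data files."""

from __future__ import annotations

import numpy as np
import pytest

from canophot import architecture, canopy
from canophot.architecture import LeafGeom, PlantModel, TriMesh


@pytest.fixture(scope="session")
def structure_table():
    return architecture.default_structure_table()


@pytest.fixture(scope="session")
def node_spec(structure_table):
    return architecture.expand_layer_spec(structure_table)


@pytest.fixture(scope="session")
def plant(node_spec):
    return architecture.build_plant(node_spec, seed=1)


@pytest.fixture(scope="session")
def assignment(plant):
    return canopy.assign_layers(plant)


def square_leaf(z: float, size: float = 1.0, leaf_id: int = 0,
                center=(0.0, 0.0), tilt_deg: float = 0.0) -> LeafGeom:
    """A flat square leaf of given size at height z, optionally tilted about
    the y-axis."""
    s = size / 2.0
    v = np.array([[-s, -s, 0.0], [s, -s, 0.0], [s, s, 0.0], [-s, s, 0.0]])
    if tilt_deg:
        a = np.radians(tilt_deg)
        rot = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                        [-np.sin(a), 0, np.cos(a)]])
        v = v @ rot.T
    v = v + np.array([center[0], center[1], z])
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return LeafGeom(leaf_id, 1, 0, TriMesh(v, f), size * size, 0.0, tilt_deg)


def leaves_plant(leaves) -> PlantModel:
    """Wrap bare leaves in a PlantModel with empty stems."""
    empty = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    return PlantModel(stems=[empty, empty], leaves=list(leaves))
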