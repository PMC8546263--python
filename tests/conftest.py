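"""Shared geometric fixtures, generated programmatically at test time."""

from __future__ import annotations

import math

import numpy as np
import pytest
import trimesh

from plaquegeom.geometry_models import Model1Params, Model2Params
from plaquegeom.mesh_synthesis import MeshResolution, mesh_from_model1, mesh_from_model2

FINE = MeshResolution(256, 64, 8)


def build_capped_cylinder(
    radius: float = 1.0, height: float = 3.0, n_phi: int = 96, n_z: int = 48
) -> trimesh.Trimesh:
    """Watertight solid cylinder with near-isotropic wall triangles.

    Library cylinder primitives use full-height wall quads, whose extreme
    anisotropy ruins graph-geodesic accuracy; this builder subdivides the
    wall axially.
    """
    phis = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    zs = np.linspace(-height / 2.0, height / 2.0, n_z + 1)
    ring = np.column_stack([radius * np.cos(phis), radius * np.sin(phis)])
    verts = np.concatenate(
        [np.column_stack([ring.repeat(1, axis=0), np.full(n_phi, z)]) for z in zs]
    )
    faces = []
    for i in range(n_z):
        for j in range(n_phi):
            a = i * n_phi + j
            b = i * n_phi + (j + 1) % n_phi
            c = (i + 1) * n_phi + (j + 1) % n_phi
            d = (i + 1) * n_phi + j
            faces += [[a, b, c], [a, c, d]]
    cb = len(verts)
    ct = cb + 1
    verts = np.vstack([verts, [0.0, 0.0, -height / 2.0], [0.0, 0.0, height / 2.0]])
    for j in range(n_phi):
        faces.append([cb, (j + 1) % n_phi, j])
        faces.append([ct, n_z * n_phi + j, n_z * n_phi + (j + 1) % n_phi])
    mesh = trimesh.Trimesh(verts, np.asarray(faces), process=False)
    assert mesh.is_watertight
    if mesh.volume < 0:
        mesh.invert()
    return mesh


@pytest.fixture(scope="session")
def unit_cube() -> trimesh.Trimesh:
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def unit_sphere() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def capped_cylinder() -> trimesh.Trimesh:
    return build_capped_cylinder()


@pytest.fixture(scope="session")
def ring_mesh_fine() -> trimesh.Trimesh:
    """Straight annular ring R=2, r=1, h=10 at fine resolution."""
    return mesh_from_model1(Model1Params(2.0, 1.0, 10.0), FINE)


@pytest.fixture(scope="session")
def half_ring_mesh_fine() -> trimesh.Trimesh:
    """Half ring R=2, r=1, h=10, theta=pi at fine resolution."""
    return mesh_from_model2(Model2Params(2.0, 1.0, 10.0, math.pi), FINE)
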