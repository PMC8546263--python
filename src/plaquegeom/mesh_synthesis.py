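"""Triangulated surface meshes realizing the idealized plaque shells.

Meshes are built by sweeping a closed cross-sectional profile (the
radial/axial outline of the shell wall) around the vessel axis: a full
periodic sweep for the slanted ring (Model 1, torus topology) and a
partial sweep capped with two flat radial side faces for the partial ring
(Model 2, sphere topology).  Because each mesh realizes a known parameter
set, discrete volume and area converge to the closed forms of
:mod:`plaquegeom.geometry_models`, which is the oracle the mesh pipeline
is tested against.

Calcifications are modelled as subdivided ellipsoids with optional seeded
smooth radial noise — real calcifications range from small spherical
specks to large irregular masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from plaquegeom.geometry_models import (
    InvalidParameterError,
    Model1Params,
    Model2Params,
)

__all__ = [
    "MeshResolution",
    "mesh_from_model1",
    "mesh_from_model2",
    "make_calcification",
    "model_centerline",
]


@dataclass(frozen=True)
class MeshResolution:
    """Discretization of a shell mesh.

    n_circ : circumferential segments (>= 16)
    n_axial : axial segments on each lateral wall (>= 4)
    n_radial : radial segments across each end face (>= 2)
    """

    n_circ: int = 128
    n_axial: int = 32
    n_radial: int = 4

    def __post_init__(self) -> None:
        if self.n_circ < 16 or self.n_axial < 4 or self.n_radial < 2:
            raise InvalidParameterError(
                "resolution requires n_circ >= 16, n_axial >= 4, n_radial >= 2; "
                f"got ({self.n_circ}, {self.n_axial}, {self.n_radial})"
            )


def _profile_loop(res: MeshResolution) -> tuple[np.ndarray, np.ndarray]:
    """Closed profile parameterization in (radial fraction, axial fraction).

    Returns arrays (rho_frac, z_frac) of length 2*(n_axial + n_radial)
    tracing: outer wall bottom->top, top face outer->inner, inner wall
    top->bottom, bottom face inner->outer.  rho_frac in [0, 1] maps
    r..R; z_frac in [0, 1] maps the local bottom..top plane.
    """
    na, nr = res.n_axial, res.n_radial
    rho = np.concatenate(
        [
            np.ones(na),                      # outer wall (rho = R)
            np.linspace(1.0, 0.0, nr + 1)[:-1],  # top face R -> r
            np.zeros(na),                     # inner wall (rho = r)
            np.linspace(0.0, 1.0, nr + 1)[:-1],  # bottom face r -> R
        ]
    )
    z = np.concatenate(
        [
            np.linspace(0.0, 1.0, na + 1)[:-1],  # bottom -> top
            np.ones(nr),
            np.linspace(1.0, 0.0, na + 1)[:-1],  # top -> bottom
            np.zeros(nr),
        ]
    )
    return rho, z


def _shell_vertices(
    p: Model1Params | Model2Params, phis: np.ndarray, res: MeshResolution
) -> np.ndarray:
    """Vertex grid (n_phi, n_prof, 3) of the swept shell profile."""
    rho_f, z_f = _profile_loop(res)
    rho = p.r + rho_f * (p.R - p.r)  # (n_prof,)
    x = np.outer(np.cos(phis), rho)  # (n_phi, n_prof)
    y = np.outer(np.sin(phis), rho)
    if isinstance(p, Model1Params):
        # end planes z_top = h/2 + x tan(theta1), z_bot = -h/2 - x tan(theta2)
        z_top = 0.5 * p.h + x * math.tan(p.theta1)
        z_bot = -0.5 * p.h - x * math.tan(p.theta2)
    else:
        z_top = np.full_like(x, 0.5 * p.h)
        z_bot = np.full_like(x, -0.5 * p.h)
    z = z_bot + z_f[None, :] * (z_top - z_bot)
    return np.stack([x, y, z], axis=-1)


def _grid_quads(n_phi: int, n_prof: int, periodic_phi: bool) -> np.ndarray:
    """Triangulated quad faces of a (phi x profile) vertex grid.

    The profile direction is always periodic (closed loop); the azimuth
    direction is periodic for the full ring only.
    """
    ii = np.arange(n_phi if periodic_phi else n_phi - 1)
    jj = np.arange(n_prof)
    i0, j0 = np.meshgrid(ii, jj, indexing="ij")
    i1 = (i0 + 1) % n_phi
    j1 = (j0 + 1) % n_prof
    a = i0 * n_prof + j0
    b = i1 * n_prof + j0
    c = i1 * n_prof + j1
    d = i0 * n_prof + j1
    tris = np.concatenate(
        [
            np.stack([a, b, c], axis=-1).reshape(-1, 3),
            np.stack([a, c, d], axis=-1).reshape(-1, 3),
        ]
    )
    return tris


def _finalize(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Weld, orient outward and validate a generated mesh."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.merge_vertices(digits_vertex=9)
    mesh.update_faces(mesh.nondegenerate_faces(height=1e-12))
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise InvalidParameterError(
            "generated mesh is not watertight "
            f"({len(mesh.edges_sorted) - len(mesh.edges_unique)} duplicate edges); "
            "parameters may be too extreme for this resolution"
        )
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def mesh_from_model1(p: Model1Params, res: MeshResolution | None = None) -> trimesh.Trimesh:
    """Watertight mesh of the slanted full ring (torus topology).

    Inner/outer lateral walls are cylinders of radii ``r`` and ``R``
    about the z-axis; the end faces lie in the planes
    ``z = h/2 + x tan(theta1)`` and ``z = -h/2 - x tan(theta2)``.
    """
    if not p.check_extent:
        # re-validate: a meshable solid needs non-intersecting end planes
        Model1Params(p.R, p.r, p.h, p.theta1, p.theta2)
    res = res or MeshResolution()
    phis = np.linspace(0.0, 2.0 * math.pi, res.n_circ, endpoint=False)
    grid = _shell_vertices(p, phis, res)
    n_phi, n_prof, _ = grid.shape
    faces = _grid_quads(n_phi, n_prof, periodic_phi=True)
    return _finalize(grid.reshape(-1, 3), faces)


def mesh_from_model2(p: Model2Params, res: MeshResolution | None = None) -> trimesh.Trimesh:
    """Watertight mesh of the partial ring (sphere topology).

    The shell spans azimuth ``[0, theta]``; the sweep is capped by two
    flat radial side faces (rectangles in the (rho, z) half-plane),
    triangulated by a fan from each cap centroid.
    """
    if p.theta >= 2.0 * math.pi:
        raise InvalidParameterError(
            "mesh_from_model2 requires theta < 2*pi (side faces must exist); "
            "use mesh_from_model1 for a full ring"
        )
    res = res or MeshResolution()
    phis = np.linspace(0.0, p.theta, res.n_circ + 1)
    grid = _shell_vertices(p, phis, res)
    n_phi, n_prof, _ = grid.shape
    faces = _grid_quads(n_phi, n_prof, periodic_phi=False)

    verts = grid.reshape(-1, 3)
    # cap each open end with a centroid fan over its profile loop
    cap_faces = []
    cap_verts = []
    for side, row in ((0, 0), (1, n_phi - 1)):
        loop = np.arange(row * n_prof, (row + 1) * n_prof)
        centroid = verts[loop].mean(axis=0)
        c_idx = len(verts) + len(cap_verts)
        cap_verts.append(centroid)
        nxt = np.roll(loop, -1)
        tri = np.stack([loop, nxt, np.full(n_prof, c_idx)], axis=-1)
        if side == 1:
            tri = tri[:, ::-1]
        cap_faces.append(tri)
    verts = np.vstack([verts, np.array(cap_verts)])
    faces = np.vstack([faces, *cap_faces])
    return _finalize(verts, faces)


def make_calcification(
    center: np.ndarray | tuple[float, float, float],
    semi_axes: np.ndarray | tuple[float, float, float],
    irregularity: float = 0.0,
    seed: int | None = None,
    subdivisions: int = 3,
    smoothing_passes: int = 10,
) -> trimesh.Trimesh:
    """Ellipsoidal calcification blob with seeded smooth radial noise.

    The unit icosphere is scaled by ``semi_axes``, then each vertex is
    displaced radially (from the center) by smoothed Gaussian noise whose
    maximal relative amplitude equals ``irregularity``.  Amplitudes below
    0.5 keep the surface star-shaped about the center, so the mesh stays
    watertight and self-intersection free.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise InvalidParameterError(f"semi_axes must be positive, got {semi_axes}")
    if not (0.0 <= irregularity < 0.5):
        raise InvalidParameterError(
            f"irregularity must be in [0, 0.5), got {irregularity}"
        )
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = sphere.vertices * semi_axes[None, :]
    if irregularity > 0.0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(len(verts))
        # neighbor-average smoothing yields low-frequency lobes, not spikes
        adj = sphere.vertex_neighbors
        for _ in range(smoothing_passes):
            noise = np.array([noise[n].mean() for n in adj]) * 0.5 + noise * 0.5
        peak = np.abs(noise).max()
        if peak > 0:
            noise = noise / peak * irregularity
        verts = verts * (1.0 + noise[:, None])
    verts = verts + np.asarray(center, dtype=float)[None, :]
    return _finalize(verts, sphere.faces.copy())


def model_centerline(
    p: Model1Params | Model2Params, n_samples: int = 32
) -> np.ndarray:
    """Straight z-axis centerline spanning the full axial extent.

    For Model 1 the extent includes the slant extensions: the end planes
    reach ``z = ±(h/2 + R tan(theta))`` at ``x = +R``.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if isinstance(p, Model1Params):
        z_max = 0.5 * p.h + p.R * math.tan(p.theta1)
        z_min = -0.5 * p.h - p.R * math.tan(p.theta2)
    else:
        z_max = 0.5 * p.h
        z_min = -0.5 * p.h
    z = np.linspace(z_min, z_max, n_samples)
    pts = np.zeros((n_samples, 3))
    pts[:, 2] = z
    return pts
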