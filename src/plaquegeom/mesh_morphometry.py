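"""Multidimensional geometric parameters of a closed triangle mesh.

For every plaque or calcification surface, six quantities characterize
size and shape across dimensions:

* volume (mm^3) — signed tetrahedron sum (divergence theorem),
* surface area (mm^2) — sum of triangle areas,
* length (mm) — longest straight-line distance between two surface
  points, operationalized as the mesh diameter (max vertex pair,
  computed exactly on the convex hull),
* surface distance (mm) — length of the shortest path on the surface
  between the two endpoints realizing the length; always >= length,
* cross-section area (mm^2) and diameter (mm) — the planar section of
  the mesh perpendicular to the vessel centerline, at the station where
  the section area is maximal (plaques only; calcifications sit in
  arbitrary orientations and carry no meaningful centerline).

Surface distances use a Steiner-refined surface graph (mesh vertices plus
edge midpoints, complete within each face) and Dijkstra shortest paths;
accuracy is 1-2 percent, which resolves the few-percent gap between
surface distance and chord length seen on real plaques.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GeometricProfile",
    "MeshValidityError",
    "mesh_volume",
    "mesh_surface_area",
    "mesh_length",
    "surface_distance",
    "cross_section_profile",
    "measure_profile",
]


class MeshValidityError(ValueError):
    """The mesh violates a precondition (open edges, empty section, ...)."""


@dataclass(frozen=True)
class GeometricProfile:
    """Measured multidimensional parameters of one object (mm-based).

    Cross-section fields are None when no centerline is supplied
    (calcifications).  Invariant: surface_distance >= length.
    """

    volume: float
    surface_area: float
    length: float
    surface_distance: float
    endpoint_pair: tuple[int, int]
    cross_section_area: float | None = None
    cross_section_diameter: float | None = None


def _require_watertight(m: trimesh.Trimesh) -> None:
    if not m.is_watertight:
        raise MeshValidityError(
            "mesh is not watertight (has boundary or non-manifold edges): "
            f"{len(m.edges_sorted)} directed edges vs {len(m.edges_unique)} unique"
        )


def mesh_volume(m: trimesh.Trimesh) -> float:
    """Enclosed volume in mm^3 via the signed-tetrahedron (divergence) sum."""
    _require_watertight(m)
    v = float(m.volume)
    if v < 0:
        raise MeshValidityError(
            "mesh is oriented inward (signed volume < 0); call mesh.invert()"
        )
    return v


def mesh_surface_area(m: trimesh.Trimesh) -> float:
    """Total surface area in mm^2 (sum of triangle areas)."""
    return float(m.area)


def _near_max_pairs(
    m: trimesh.Trimesh, rel_tol: float = 1e-9
) -> tuple[float, list[tuple[int, int]]]:
    """Mesh diameter and every vertex pair realizing it within rel_tol.

    Symmetric objects realize their diameter at several pairs; all are
    returned (sorted) so callers can treat them interchangeably.
    """
    verts = np.asarray(m.vertices)
    if len(verts) < 2:
        raise MeshValidityError("mesh has fewer than 2 vertices")
    try:
        hull_idx = np.unique(ConvexHull(verts).vertices)
    except Exception:  # degenerate (flat) meshes: fall back to all vertices
        hull_idx = np.arange(len(verts))
    d = squareform(pdist(verts[hull_idx]))
    best = float(d.max())
    ties = np.argwhere(d >= best * (1.0 - rel_tol))
    pairs = sorted(
        {
            tuple(sorted((int(hull_idx[a]), int(hull_idx[b]))))
            for a, b in ties
            if a != b
        }
    )
    return best, pairs


def mesh_length(m: trimesh.Trimesh) -> tuple[float, tuple[int, int]]:
    """Mesh diameter: max Euclidean distance over all vertex pairs.

    The maximum is attained on convex-hull vertices, so the pairwise
    search is restricted to them (exact, not sampled).  Returns the
    distance and the realizing vertex-index pair; near-ties broken by
    lowest indices.
    """
    best, pairs = _near_max_pairs(m)
    return best, pairs[0]


def _surface_graph(m: trimesh.Trimesh) -> tuple[coo_matrix, np.ndarray]:
    """Steiner-refined surface graph: vertices + edge midpoints.

    Within each triangle all 6 nodes (3 corners + 3 edge midpoints) are
    pairwise connected; midpoints are shared across the two faces of
    each interior edge.  Returns the sparse weighted adjacency and the
    node coordinate array (first len(m.vertices) nodes are the original
    vertices).
    """
    verts = np.asarray(m.vertices)
    edges = m.edges_unique  # (E, 2) sorted vertex pairs
    mid_coords = verts[edges].mean(axis=1)
    nodes = np.vstack([verts, mid_coords])
    n_v = len(verts)

    # map each face's 3 edges to midpoint node ids
    face_edge_mid = m.faces_unique_edges + n_v  # (F, 3)
    faces = m.faces
    # node ids per face: corners (0,1,2) then midpoints of edges
    per_face = np.hstack([faces, face_edge_mid])  # (F, 6)
    ii, jj = np.triu_indices(6, k=1)
    a = per_face[:, ii].ravel()
    b = per_face[:, jj].ravel()
    w = np.linalg.norm(nodes[a] - nodes[b], axis=1)
    keep = w > 0
    a, b, w = a[keep], b[keep], w[keep]
    n = len(nodes)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    # edges shared between adjacent faces appear twice with equal weight;
    # deduplicate so the csr build does not sum them
    key = lo.astype(np.int64) * n + hi
    _, first = np.unique(key, return_index=True)
    a, b, w = lo[first], hi[first], w[first]
    adj = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([a, b]), np.concatenate([b, a]))),
        shape=(n, n),
    ).tocsr()
    return adj, nodes


def surface_distance(
    m: trimesh.Trimesh,
    a: np.ndarray | tuple[float, float, float] | int,
    b: np.ndarray | tuple[float, float, float] | int,
) -> float:
    """Shortest on-surface path length (mm) between two surface points.

    Points given as coordinates are snapped to the nearest mesh vertex.
    The result is always >= the Euclidean distance |a - b|.
    """
    verts = np.asarray(m.vertices)

    def _snap(p) -> int:
        if isinstance(p, (int, np.integer)):
            return int(p)
        p = np.asarray(p, dtype=float)
        return int(np.argmin(np.linalg.norm(verts - p[None, :], axis=1)))

    ia, ib = _snap(a), _snap(b)
    if ia == ib:
        return 0.0
    adj, _nodes = _surface_graph(m)
    dist = dijkstra(adj, directed=False, indices=ia, min_only=True)
    d = float(dist[ib])
    if not np.isfinite(d):
        raise MeshValidityError(
            "no on-surface path: the two points lie on disconnected components"
        )
    return d


def _section_loops(
    m: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray
) -> list[np.ndarray]:
    """Closed intersection polylines of the mesh with a plane (world 3D)."""
    section = m.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        return []
    return [np.asarray(d, dtype=float) for d in section.discrete]


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane axes for a unit normal."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _even_odd_area(loops_uv: list[np.ndarray]) -> float:
    """Total enclosed planar area of closed loops with even-odd holes.

    Each loop contributes +area at even nesting depth and -area at odd
    depth (a hole), so full-ring sections report the annulus area.
    """
    from shapely.geometry import Point, Polygon

    polys = [Polygon(lp) for lp in loops_uv if len(lp) >= 3]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    total = 0.0
    for i, poly in enumerate(polys):
        probe = Point(np.asarray(loops_uv[i][0]))
        depth = sum(
            1 for j, other in enumerate(polys) if j != i and other.contains(probe)
        )
        total += poly.area * (-1.0) ** depth
    return total


def _polyline_tangents(centerline: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the endpoints)."""
    c = np.asarray(centerline, dtype=float)
    t = np.gradient(c, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("centerline has repeated consecutive points")
    return t / norms


def cross_section_profile(
    m: trimesh.Trimesh,
    centerline: np.ndarray,
    n_stations: int = 25,
) -> tuple[float, float, int]:
    """Maximal perpendicular cross-section along the vessel centerline.

    At ``n_stations`` stations equally spaced along the polyline, the
    mesh is sliced by the plane normal to the local tangent; the section
    area is the total enclosed planar area (holes subtracted, even-odd).
    Returns ``(max_area_mm2, diameter_mm, station_index)`` where the
    diameter is the longest distance between points of the maximal
    section.
    """
    c = np.asarray(centerline, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] != 3:
        raise ValueError("centerline must be an (n>=2, 3) polyline")
    if n_stations < 3:
        raise ValueError(f"n_stations must be >= 3, got {n_stations}")
    _require_watertight(m)

    # arc-length resample to n_stations, tangents from the resampled curve
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n_stations)
    pts = np.column_stack([np.interp(si, s, c[:, k]) for k in range(3)])
    tangents = _polyline_tangents(pts)

    best = (-1.0, 0.0, -1)
    for idx in range(n_stations):
        loops = _section_loops(m, pts[idx], tangents[idx])
        if not loops:
            continue
        u, v = _plane_basis(tangents[idx])
        loops_uv = [np.column_stack([lp @ u, lp @ v]) for lp in loops]
        area = _even_odd_area(loops_uv)
        if area > best[0]:
            pts3d = np.vstack(loops)
            diam = float(pdist(pts3d).max()) if len(pts3d) >= 2 else 0.0
            best = (area, diam, idx)
    if best[2] < 0:
        raise MeshValidityError(
            "no station's section plane intersects the mesh; "
            "check that the centerline passes through the object"
        )
    return best


def measure_profile(
    m: trimesh.Trimesh,
    centerline: np.ndarray | None = None,
    n_stations: int = 25,
) -> GeometricProfile:
    """Assemble the full geometric profile of one object.

    The surface distance is measured between the vertices realizing the
    length; when several pairs tie for the diameter (symmetric objects)
    the shortest of their surface paths is reported, which makes the
    profile invariant to rigid motion.  Cross-section fields are
    populated only when a centerline is given.
    """
    V = mesh_volume(m)
    S = mesh_surface_area(m)
    L, pairs = _near_max_pairs(m)
    sd = min(surface_distance(m, a, b) for a, b in pairs)
    pair = pairs[0]
    xsec_area = xsec_diam = None
    if centerline is not None:
        xsec_area, xsec_diam, _ = cross_section_profile(m, centerline, n_stations)
    return GeometricProfile(
        volume=V,
        surface_area=S,
        length=L,
        surface_distance=sd,
        endpoint_pair=pair,
        cross_section_area=xsec_area,
        cross_section_diameter=xsec_diam,
    )
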