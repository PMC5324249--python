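"""Interior centerline extraction and its differential geometry.

The centerline is the weighted shortest path between two extremal points,
with edge costs penalizing wall proximity so the path rides the locus of
maximal inscribed spheres: the interior is voxelized, a Euclidean distance
transform supplies the wall distance ``d`` at every interior voxel, and a
Dijkstra search minimizes ``sum(step_length / d^p)`` (p = 2 by default).
A cross-section-centroid refinement pass then removes the voxel-center
quantization, giving sub-voxel centrality on tubular lumens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ._geometry import (
    MeshDistanceQuery,
    plane_basis,
    plane_section_polylines,
    polyline_arc_length,
    polyline_tangents,
    resample_polyline,
    rim_aligned_rotation,
    voxelize_interior,
)
from .mesh_core import SurfaceMesh

__all__ = [
    "Centerline",
    "CenterlineGeometry",
    "CenterlineError",
    "compute_centerline",
    "smooth_centerline",
    "geometry",
]


class CenterlineError(RuntimeError):
    pass


@dataclass
class Centerline:
    """Ordered interior polyline with arc length, inscribed radius, tangents."""

    points: np.ndarray  # (n, 3) mm
    arc_length: np.ndarray  # (n,) mm, strictly increasing from 0
    inscribed_radius: np.ndarray  # (n,) mm, distance to the lumen wall
    tangents: np.ndarray  # (n, 3) unit vectors

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s, self.arc_length, self.points[:, j]) for j in range(3)]
        )
        return out

    def tangent_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        t = np.column_stack(
            [np.interp(s, self.arc_length, self.tangents[:, j]) for j in range(3)]
        )
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.where(norms > 0, norms, 1.0)

    def resampled(self, step: float) -> "Centerline":
        pts = resample_polyline(self.points, step)
        s = polyline_arc_length(pts)
        radius = np.interp(s, self.arc_length, self.inscribed_radius)
        return Centerline(pts, s, radius, polyline_tangents(pts))

    def to_frame(self):
        """Per-point table (s, x, y, z, r_inscribed) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "s_mm": self.arc_length,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "r_inscribed_mm": self.inscribed_radius,
            }
        )


@dataclass
class CenterlineGeometry:
    """Scalar shape descriptors of one centerline."""

    tortuosity: float  # arc length / endpoint chord, >= 1
    curvature_profile: np.ndarray  # 1/mm per point, >= 0
    apex_index: int  # station maximizing the elevation coordinate

    @property
    def apex_curvature(self) -> float:
        return float(self.curvature_profile[self.apex_index])


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
)


def compute_centerline(
    mesh: SurfaceMesh,
    source,
    target,
    pitch: Optional[float] = None,
    power: float = 2.0,
    step: float = 0.5,
    refine_iterations: int = 2,
) -> Centerline:
    """Trace the centerline between two extremal points of the lumen.

    Parameters
    ----------
    mesh : lumen surface (closed, or open at the inlet/outlet rims).
    source, target : 3D points on or near the two openings.
    pitch : voxel pitch for the interior graph, mm.  Defaults to 1 mm,
        reduced for small lumens (about a fifth of the narrowest extent).
    power : wall-distance exponent in the edge cost; larger values pull the
        path harder toward the medial locus.
    step : resampling step of the returned polyline, mm.
    refine_iterations : cross-section-centroid refinement passes.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    _check_distinct_openings(mesh, source, target)
    tm = mesh.to_trimesh()
    if pitch is None:
        pitch = float(min(1.0, max(np.min(tm.extents) / 10.0, 0.05)))

    # rasterize in a rim-aligned frame so slice planes never cross the
    # open rims however the mesh is oriented in world coordinates
    import trimesh as _trimesh

    frame = rim_aligned_rotation(tm)
    tm_frame = (
        tm
        if np.allclose(frame, np.eye(3))
        else _trimesh.Trimesh(tm.vertices @ frame.T, tm.faces, process=False)
    )
    source_f = frame @ source
    target_f = frame @ target

    mask, origin = voxelize_interior(tm_frame, pitch)
    if not mask.any():
        raise CenterlineError("voxelized interior is empty; check mesh or pitch")
    wall = ndimage.distance_transform_edt(mask, sampling=pitch)

    interior = np.flatnonzero(mask.ravel())
    node_of = -np.ones(mask.size, dtype=np.int64)
    node_of[interior] = np.arange(len(interior))
    shape = mask.shape
    coords = np.column_stack(np.unravel_index(interior, shape))
    wall_flat = wall.ravel()[interior]

    rows, cols, data = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        nb = coords + off
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        nb_node = node_of[nb_flat]
        valid = nb_node >= 0
        src_node = np.flatnonzero(ok)[valid]
        dst_node = nb_node[valid]
        length = np.linalg.norm(off) * pitch
        mean_d = 0.5 * (wall_flat[src_node] + wall_flat[dst_node])
        cost = length / np.maximum(mean_d, pitch / 4) ** power
        rows.append(src_node)
        cols.append(dst_node)
        data.append(cost)
    graph = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(interior), len(interior)),
    )
    graph = graph + graph.T  # symmetric

    centers = origin + coords * pitch
    tree = cKDTree(centers)
    _, i_src = tree.query(source_f)
    _, i_dst = tree.query(target_f)
    dist, pred = dijkstra(
        graph, directed=False, indices=i_src, return_predecessors=True
    )
    if not np.isfinite(dist[i_dst]):
        raise CenterlineError(
            "no interior path between source and target (disconnected lumen?)"
        )
    path = [i_dst]
    while path[-1] != i_src:
        path.append(pred[path[-1]])
    path = np.asarray(path[::-1])
    points = centers[path] @ frame  # back to world coordinates
    # extend to the requested extremal points (the voxel path stops at the
    # nearest interior voxel center, truncating the arc by up to one pitch)
    if 1e-9 < np.linalg.norm(points[0] - source) <= 5 * pitch:
        points = np.vstack([source, points])
    if 1e-9 < np.linalg.norm(points[-1] - target) <= 5 * pitch:
        points = np.vstack([points, target])

    points = resample_polyline(points, step)
    points = _moving_average(points, window=max(3 * pitch, 2 * step))
    query = MeshDistanceQuery(tm)
    for _ in range(max(refine_iterations, 0)):
        points = _centroid_refine(tm, points, max_shift=3 * pitch)
        points = resample_polyline(points, step)

    s = polyline_arc_length(points)
    _, radius, _ = query.query(points)
    return Centerline(points, s, radius, polyline_tangents(points))


def _check_distinct_openings(mesh: SurfaceMesh, source, target):
    loops = mesh.boundary_loops
    if len(loops) >= 2:
        def nearest_loop(p):
            best, best_d = -1, np.inf
            for i, loop in enumerate(loops):
                d = np.linalg.norm(mesh.vertices[loop] - p, axis=1).min()
                if d < best_d:
                    best, best_d = i, d
            return best

        if nearest_loop(source) == nearest_loop(target):
            raise CenterlineError(
                "source and target lie on the same boundary opening"
            )


def _moving_average(points: np.ndarray, window: float) -> np.ndarray:
    """Arc-length moving average with the window shrinking to zero at the
    endpoints, which pins them in place."""
    s = polyline_arc_length(points)
    total = s[-1]
    out = np.empty_like(points)
    for i, si in enumerate(s):
        half = min(window / 2, si, total - si)
        if half <= 0:
            out[i] = points[i]
            continue
        sel = (s >= si - half) & (s <= si + half)
        out[i] = points[sel].mean(axis=0)
    return out


def _centroid_refine(tm, points: np.ndarray, max_shift: float = 3.0) -> np.ndarray:
    """Move each point to the area centroid of its normal cross-section.

    Shifts larger than ``max_shift`` are rejected: the input is already
    within a voxel pitch of the medial locus, so a large proposed move means
    the section plane grazed an open rim or caught a different limb of the
    vessel, not a genuine correction.
    """
    from shapely.geometry import Point, Polygon

    tangents = polyline_tangents(points)
    out = points.copy()
    for i in range(len(points)):
        polylines = plane_section_polylines(tm, points[i], tangents[i])
        if not polylines:
            continue
        u, v = plane_basis(tangents[i])
        best_poly, best_d = None, np.inf
        p2 = np.array([points[i] @ u, points[i] @ v])
        for loop in polylines:
            if len(loop) < 4 or not np.allclose(loop[0], loop[-1]):
                continue
            loop2 = np.column_stack([loop @ u, loop @ v])
            poly = Polygon(loop2)
            if not poly.is_valid or poly.area <= 0:
                continue
            d = 0.0 if poly.contains(Point(p2)) else poly.exterior.distance(Point(p2))
            if d < best_d:
                best_poly, best_d = poly, d
        if best_poly is None:
            continue
        c = best_poly.centroid
        w = points[i] @ tangents[i]
        candidate = c.x * u + c.y * v + w * tangents[i]
        if np.linalg.norm(candidate - points[i]) <= max_shift:
            out[i] = candidate
    return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_centerline(
    cl: Centerline, window: float, mesh: Optional[SurfaceMesh] = None
) -> Centerline:
    """Moving-average smoothing over an arc-length window, endpoints pinned.

    If ``mesh`` is given, smoothed points that leave the lumen are pulled
    back just inside the nearest wall.  Arc length, tangents and inscribed
    radius are re-derived (exactly when a mesh is supplied, otherwise by
    interpolation from the input).
    """
    points = _moving_average(cl.points, window)
    if mesh is not None:
        tm = mesh.to_trimesh()
        query = MeshDistanceQuery(tm)
        closest, dist, tid = query.query(points)
        normals = tm.face_normals[tid]
        outside = np.einsum("ij,ij->i", points - closest, normals) > 0
        if outside.any():
            inward = 0.25  # mm
            points[outside] = closest[outside] - inward * normals[outside]
        s = polyline_arc_length(points)
        _, radius, _ = query.query(points)
        return Centerline(points, s, radius, polyline_tangents(points))
    s = polyline_arc_length(points)
    radius = np.interp(s, cl.arc_length, cl.inscribed_radius)
    return Centerline(points, s, radius, polyline_tangents(points))


# ---------------------------------------------------------------------------
# differential geometry
# ---------------------------------------------------------------------------

def geometry(
    cl: Centerline, elevation_axis=(0.0, 0.0, 1.0), stencil: float = 2.0
) -> CenterlineGeometry:
    """Tortuosity, per-station curvature, and the arch-apex station.

    Tortuosity is total arc length over the endpoint chord.  Curvature uses
    the circumscribed circle of three points ``stencil`` mm apart (the
    stencil matching the 2 mm plane spacing keeps noise amplification in
    check).  The apex is the station with the largest coordinate along
    ``elevation_axis`` — for a supine scan this is the superior-most point
    of the arch.
    """
    if len(cl.points) < 3:
        raise ValueError("need at least 3 centerline points")
    chord = float(np.linalg.norm(cl.points[-1] - cl.points[0]))
    if chord < 1e-9:
        raise ValueError("coincident endpoints: tortuosity undefined")
    tortuosity = cl.length / chord

    s = cl.arc_length
    curvature = np.zeros(len(s))
    for i, si in enumerate(s):
        s0, s2 = si - stencil, si + stencil
        if s0 < 0:
            s0, s2 = 0.0, min(2 * stencil, s[-1])
        elif s2 > s[-1]:
            s0, s2 = max(s[-1] - 2 * stencil, 0.0), s[-1]
        p0 = cl.point_at(s0)[0]
        p1 = cl.point_at((s0 + s2) / 2)[0]
        p2 = cl.point_at(s2)[0]
        curvature[i] = _three_point_curvature(p0, p1, p2)

    axis = np.asarray(elevation_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    apex = int(np.argmax(cl.points @ axis))
    return CenterlineGeometry(
        tortuosity=float(tortuosity), curvature_profile=curvature, apex_index=apex
    )


def _three_point_curvature(p0, p1, p2) -> float:
    """Reciprocal circumradius of a point triple (0 for collinear points)."""
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p2 - p0)
    cross = np.linalg.norm(np.cross(p1 - p0, p2 - p0))
    denom = a * b * c
    if denom < 1e-12:
        return 0.0
    return float(2.0 * cross / denom)
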