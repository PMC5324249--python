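"""Shared low-level geometry kernels.

Closest-point-on-mesh queries, interior voxelization by slice rasterization,
polyline resampling and parallel-transport frames.  Everything here is plain
numpy/scipy; meshes arrive as ``trimesh.Trimesh`` objects.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_triangles",
    "closest_point_on_mesh",
    "closest_point_on_mesh_brute",
    "points_in_mesh",
    "voxelize_interior",
    "polyline_arc_length",
    "resample_polyline",
    "polyline_tangents",
    "parallel_transport_frames",
    "plane_basis",
]


# ---------------------------------------------------------------------------
# point / triangle distance
# ---------------------------------------------------------------------------

def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (paired, vectorized).

    Parameters
    ----------
    points : (n, 3) query points.
    triangles : (n, 3, 3) triangle vertices paired with the query points.

    Returns
    -------
    (n, 3) closest points.  Exact: the minimum over the in-plane projection
    (when its barycentric coordinates are non-negative) and the three edges.
    """
    points = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    # candidate 1..3: closest point on each edge segment
    candidates = []
    for p0, p1 in ((a, b), (b, c), (c, a)):
        d = p1 - p0
        denom = np.einsum("ij,ij->i", d, d)
        t = np.einsum("ij,ij->i", points - p0, d) / np.where(denom > 0, denom, 1.0)
        t = np.clip(t, 0.0, 1.0)
        candidates.append(p0 + t[:, None] * d)

    # candidate 0: projection onto the triangle plane, kept only when it
    # falls inside the triangle
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    safe = nn > 0
    dist_plane = np.einsum("ij,ij->i", points - a, n) / np.where(safe, nn, 1.0)
    proj = points - dist_plane[:, None] * n
    # barycentric test via signed sub-areas
    w0 = np.einsum("ij,ij->i", np.cross(b - proj, c - proj), n)
    w1 = np.einsum("ij,ij->i", np.cross(c - proj, a - proj), n)
    w2 = np.einsum("ij,ij->i", np.cross(a - proj, b - proj), n)
    inside = safe & (w0 >= -1e-12 * nn) & (w1 >= -1e-12 * nn) & (w2 >= -1e-12 * nn)

    best = candidates[0]
    best_d2 = np.einsum("ij,ij->i", points - best, points - best)
    for cand in candidates[1:]:
        d2 = np.einsum("ij,ij->i", points - cand, points - cand)
        better = d2 < best_d2
        best = np.where(better[:, None], cand, best)
        best_d2 = np.where(better, d2, best_d2)
    d2p = np.einsum("ij,ij->i", points - proj, points - proj)
    use_proj = inside & (d2p < best_d2)
    best = np.where(use_proj[:, None], proj, best)
    return best


def closest_point_on_mesh_brute(mesh, points: np.ndarray):
    """All-triangles closest-point query; the reference for the pruned query.

    Returns (closest (n,3), distance (n,), triangle_index (n,)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles
    n_pts, n_tri = len(points), len(tris)
    closest = np.empty((n_pts, 3))
    dist = np.empty(n_pts)
    tid = np.empty(n_pts, dtype=np.intp)
    # chunk over points to bound memory at ~n_tri*chunk pairs
    chunk = max(1, int(4_000_000 / max(n_tri, 1)))
    for lo in range(0, n_pts, chunk):
        hi = min(lo + chunk, n_pts)
        p = np.repeat(points[lo:hi], n_tri, axis=0)
        t = np.tile(tris, (hi - lo, 1, 1))
        cand = closest_point_on_triangles(p, t).reshape(hi - lo, n_tri, 3)
        d2 = ((points[lo:hi, None, :] - cand) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        rows = np.arange(hi - lo)
        closest[lo:hi] = cand[rows, idx]
        dist[lo:hi] = np.sqrt(d2[rows, idx])
        tid[lo:hi] = idx
    return closest, dist, tid


class MeshDistanceQuery:
    """Exact closest-point-on-surface queries accelerated by KD-tree pruning.

    A KD-tree over triangle centroids supplies candidate triangles: any
    triangle that could beat the current best must have its centroid within
    ``best + r_max`` of the query point, where ``r_max`` is the largest
    centroid-to-vertex radius in the mesh.  The candidate set is then checked
    with the exact point-triangle kernel, so results equal the brute-force
    all-triangles answer.
    """

    def __init__(self, mesh):
        self.mesh = mesh
        tris = mesh.triangles
        self._tris = tris
        self._centroids = tris.mean(axis=1)
        self._radius = np.sqrt(
            ((tris - self._centroids[:, None, :]) ** 2).sum(axis=2).max(axis=1)
        )
        self._rmax = float(self._radius.max()) if len(tris) else 0.0
        self._tree = cKDTree(self._centroids)
        self._vtree = cKDTree(mesh.vertices)

    def query(self, points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        # upper bound: distance to the nearest mesh vertex (achievable)
        ub, _ = self._vtree.query(points)
        closest = np.empty((n, 3))
        dist = np.empty(n)
        tid = np.empty(n, dtype=np.intp)
        groups = self._tree.query_ball_point(points, ub + self._rmax + 1e-9)
        for i, cand in enumerate(groups):
            cand = np.asarray(cand, dtype=np.intp)
            p = np.broadcast_to(points[i], (len(cand), 3))
            cp = closest_point_on_triangles(p, self._tris[cand])
            d2 = ((cp - points[i]) ** 2).sum(axis=1)
            j = d2.argmin()
            closest[i] = cp[j]
            dist[i] = np.sqrt(d2[j])
            tid[i] = cand[j]
        return closest, dist, tid


def closest_point_on_mesh(mesh, points: np.ndarray):
    """One-shot pruned closest-point query; see :class:`MeshDistanceQuery`."""
    return MeshDistanceQuery(mesh).query(points)


# ---------------------------------------------------------------------------
# interior tests / voxelization
# ---------------------------------------------------------------------------

def plane_section_polylines(mesh, plane_origin, plane_normal):
    """Intersection of a mesh with a plane as chained polylines.

    Returns a list of (n, 3) arrays; closed loops have first == last point.
    Chains the raw face/plane segments by endpoint identity, which keeps
    open chains (rim or ostium crossings) that higher-level path containers
    tend to drop.
    """
    import trimesh

    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=np.asarray(plane_normal, dtype=float),
        plane_origin=np.asarray(plane_origin, dtype=float),
    )
    if len(segs) == 0:
        return []
    pts = segs.reshape(-1, 3)
    key = np.round(pts / 1e-6).astype(np.int64)
    uniq, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    coords = pts[first]
    edges = inv.reshape(-1, 2)
    edges = edges[edges[:, 0] != edges[:, 1]]
    if len(edges) == 0:
        return []
    edges = np.unique(np.sort(edges, axis=1), axis=0)

    adjacency: dict[int, list[int]] = {}
    for a, b in edges:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    used = set()

    def walk(start):
        chain = [start]
        prev = None
        node = start
        while True:
            nxt = None
            for nb in adjacency[node]:
                e = (min(node, nb), max(node, nb))
                if e not in used:
                    nxt = nb
                    used.add(e)
                    break
            if nxt is None:
                return chain
            chain.append(nxt)
            prev, node = node, nxt
            if node == start:
                return chain

    polylines = []
    # open chains first: start at odd-degree nodes
    for node, nbrs in adjacency.items():
        if len(nbrs) % 2 == 1:
            while any(
                (min(node, nb), max(node, nb)) not in used for nb in nbrs
            ):
                chain = walk(node)
                if len(chain) > 1:
                    polylines.append(coords[chain])
    # remaining cycles
    for a, b in edges:
        e = (min(a, b), max(a, b))
        if e not in used:
            chain = walk(int(a))
            if len(chain) > 1:
                polylines.append(coords[chain])
    return polylines


def _loop_polygons(discrete, other):
    """Section polylines -> shapely polygons (even-odd ingredients).

    Open polylines whose endpoint gap is small relative to their length are
    closed with a chord: they arise where a section plane grazes an open rim
    or a branch ostium hole, and the chord closure is the natural repair.
    Short fragments are dropped.
    """
    from shapely.geometry import Polygon

    polys = []
    for loop in discrete:
        if len(loop) < 4:
            continue
        if not np.allclose(loop[0], loop[-1]):
            length = np.linalg.norm(np.diff(loop, axis=0), axis=1).sum()
            gap = np.linalg.norm(loop[0] - loop[-1])
            if length <= 0 or gap > 0.5 * length:
                continue
        poly = Polygon(loop[:, other])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area <= 0:
            continue
        polys.append(poly)
    return polys


def _slice_parity_mask(mesh, grid_u, grid_v, positions, axis: int) -> np.ndarray:
    """Even-odd interior mask built slice by slice along ``axis``."""
    from shapely import contains_xy

    uu, vv = np.meshgrid(grid_u, grid_v, indexing="ij")
    mask = np.zeros((len(grid_u), len(grid_v), len(positions)), dtype=bool)
    normal = np.zeros(3)
    normal[axis] = 1.0
    other = [i for i in range(3) if i != axis]
    origin = np.zeros(3)
    for k, w in enumerate(positions):
        origin[axis] = w
        polylines = plane_section_polylines(mesh, origin, normal)
        if not polylines:
            continue
        parity = np.zeros(uu.shape, dtype=np.int64)
        for poly in _loop_polygons(polylines, other):
            parity += contains_xy(poly, uu.ravel(), vv.ravel()).reshape(uu.shape)
        mask[:, :, k] = (parity % 2) == 1
    return mask


def _boundary_loop_vertices(mesh):
    """Vertex index lists of the open rims of a trimesh (may be empty)."""
    faces = np.asarray(mesh.faces)
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(boundary.tolist())
    return [list(c) for c in nx.connected_components(g)]


def rim_aligned_rotation(mesh) -> np.ndarray:
    """Rotation taking the mean open-rim normal onto +z.

    Rasterizing the interior in this frame keeps slice planes parallel to
    the rim planes, so sections near the openings stay closed regardless of
    how the mesh is oriented in world coordinates.  Identity for closed
    meshes or when the rims disagree on a direction.
    """
    loops = _boundary_loop_vertices(mesh)
    if not loops:
        return np.eye(3)
    biggest = max(len(l) for l in loops)
    normals = []
    for loop in loops:
        if len(loop) < 0.5 * biggest:
            continue
        pts = mesh.vertices[loop]
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        n = vt[-1]
        if normals and np.dot(n, normals[0]) < 0:
            n = -n
        normals.append(n)
    mean = np.sum(normals, axis=0)
    norm = np.linalg.norm(mean)
    if norm < 0.5:
        return np.eye(3)
    n = mean / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(np.dot(n, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _pick_slice_axis(mesh) -> int:
    """Slicing axis for interior rasterization.

    Sections that cross an open rim come out as open polylines, so the best
    slicing direction is the one most parallel to the rim normals (slices
    then run parallel to the rim planes and never cross them).  For closed
    meshes fall back to the longest bounding-box axis (fewest slices of the
    tube run close to tangency).
    """
    loops = _boundary_loop_vertices(mesh)
    if not loops:
        return int(np.argmax(mesh.extents))
    # only the major openings (inlet/outlet) steer the choice; small rims
    # (branch ostia, stub bases) are handled by chord-closing open sections
    biggest = max(len(l) for l in loops)
    loops = [l for l in loops if len(l) >= 0.5 * biggest]
    normals = []
    for loop in loops:
        pts = mesh.vertices[loop]
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        normals.append(vt[-1])
    normals = np.abs(np.asarray(normals))
    # maximize the worst-case alignment with any rim normal
    return int(np.argmax(normals.min(axis=0)))


def points_in_mesh(mesh, points: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Even-odd interior test by plane sections (no BVH dependency).

    Groups the query points by their coordinate along ``axis`` and tests each
    group against the closed section loops of the mesh at that level.  Points
    are expected on a small set of distinct levels (as in voxel grids); for
    scattered points this degenerates to one section per point.
    """
    from shapely import contains_xy

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if axis is None:
        axis = _pick_slice_axis(mesh)
    other = [i for i in range(3) if i != axis]
    inside = np.zeros(len(points), dtype=bool)
    normal = np.zeros(3)
    normal[axis] = 1.0
    levels, inv = np.unique(points[:, axis], return_inverse=True)
    origin = np.zeros(3)
    for li, w in enumerate(levels):
        sel = inv == li
        origin[axis] = w
        polylines = plane_section_polylines(mesh, origin, normal)
        if not polylines:
            continue
        parity = np.zeros(sel.sum(), dtype=np.int64)
        uv = points[sel][:, other]
        for poly in _loop_polygons(polylines, other):
            parity += contains_xy(poly, uv[:, 0], uv[:, 1])
        inside[sel] = (parity % 2) == 1
    return inside


def voxelize_interior(mesh, pitch: float, margin: int = 2):
    """Binary occupancy of the mesh interior on a regular grid.

    Returns (mask (nx,ny,nz) bool, origin (3,) center of voxel [0,0,0]).
    Slicing runs along the longest bounding-box axis; slice levels are offset
    from the bounds by half a pitch so planar caps are never hit exactly.
    """
    lo, hi = mesh.bounds
    origin = lo - (margin - 0.5) * pitch
    counts = np.ceil((hi - lo) / pitch).astype(int) + 2 * margin
    axes = [origin[i] + pitch * np.arange(counts[i]) for i in range(3)]
    axis = _pick_slice_axis(mesh)
    other = [i for i in range(3) if i != axis]
    mask_ax = _slice_parity_mask(mesh, axes[other[0]], axes[other[1]], axes[axis], axis)
    # reorder (u, v, w) back to (x, y, z)
    order = np.argsort(other + [axis])
    mask = np.transpose(mask_ax, order)
    return mask, origin


# ---------------------------------------------------------------------------
# polylines and frames
# ---------------------------------------------------------------------------

def polyline_arc_length(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample at uniform arc-length spacing ``step`` (endpoints kept)."""
    s = polyline_arc_length(points)
    total = s[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    n = max(int(round(total / step)), 1)
    si = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, 3))
    for j in range(3):
        out[:, j] = np.interp(si, s, points[:, j])
    return out


def polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    points = np.asarray(points, dtype=float)
    t = np.gradient(points, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def parallel_transport_frames(points: np.ndarray):
    """Rotation-minimizing frames (e1, e2) normal to a polyline.

    Transports an initial normal along the curve by rotating with the
    tangent, avoiding the frame twist of Frenet frames at inflections.
    Returns (tangents, e1, e2), each (n, 3).
    """
    tangents = polyline_tangents(points)
    n = len(points)
    e1 = np.empty((n, 3))
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(t0, ref)
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, n):
        b = np.cross(tangents[i - 1], tangents[i])
        nb = np.linalg.norm(b)
        if nb < 1e-12:
            e1[i] = e1[i - 1]
        else:
            b = b / nb
            cos_a = np.clip(np.dot(tangents[i - 1], tangents[i]), -1.0, 1.0)
            ang = np.arccos(cos_a)
            e1[i] = _rotate_about(e1[i - 1], b, ang)
        # re-orthogonalize against drift
        e1[i] -= np.dot(e1[i], tangents[i]) * tangents[i]
        e1[i] /= np.linalg.norm(e1[i])
    e2 = np.cross(tangents, e1)
    return tangents, e1, e2


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def plane_basis(normal: np.ndarray):
    """Orthonormal (u, v) spanning the plane with the given unit normal."""
    normal = np.asarray(normal, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v
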