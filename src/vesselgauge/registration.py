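"""Rigid visit-to-visit registration and signed surface-change maps.

Two visit surfaces are aligned in two stages — a coarse least-squares fit
on user-picked landmark pairs, then iterative closest point (ICP) — and the
remaining per-vertex signed distance between them is the change map.  The
registration is deliberately rigid only: scaling or affine terms would
absorb exactly the growth the change map is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._geometry import MeshDistanceQuery
from .mesh_core import SurfaceMesh

__all__ = [
    "RigidTransform",
    "ChangeMap",
    "ICPResult",
    "RegistrationError",
    "landmark_align",
    "icp",
    "change_map",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def landmark_align(source_points, target_points) -> RigidTransform:
    """Least-squares rigid fit mapping source landmarks onto target ones
    (orthogonal Procrustes / Kabsch; no scaling, reflections rejected).

    Needs at least 3 non-collinear pairs.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    dst = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if len(src) != len(dst) or len(src) < 3:
        raise ValueError("need >= 3 corresponding point pairs")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - sc, dst - dc
    # collinearity: second singular value of the centered cloud vanishes
    if np.linalg.svd(a, compute_uv=False)[1] < 1e-9 * max(
        np.linalg.norm(a), 1.0
    ):
        raise ValueError("landmark pairs are collinear; rotation is ambiguous")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = dc - r @ sc
    return RigidTransform(r, t)


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations: int
    rms_history: list = field(default_factory=list)


def icp(
    source_points,
    target_mesh: SurfaceMesh,
    init: Optional[RigidTransform] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    rejection_factor: float = 10.0,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> ICPResult:
    """Iterative closest point refinement of a coarse rigid alignment.

    Alternates exact point-to-surface correspondences with a Kabsch fit
    until the correspondence RMS changes by less than ``tol`` mm.
    Correspondences farther than ``rejection_factor`` x median are dropped
    each iteration (robustness near clipped rims).  Raises if the RMS
    increases five iterations in a row.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    if subsample is not None and subsample < len(src):
        rng = np.random.default_rng(seed)
        src = src[rng.choice(len(src), size=subsample, replace=False)]
    transform = RigidTransform.identity() if init is None else init
    query = MeshDistanceQuery(target_mesh.to_trimesh())

    prev_rms = np.inf
    rises = 0
    history = []
    for iteration in range(1, max_iter + 1):
        moved = transform.apply(src)
        closest, dist, _ = query.query(moved)
        med = np.median(dist)
        keep = dist <= max(rejection_factor * med, 1e-12)
        if keep.sum() < 3:
            raise RegistrationError("too few correspondences after rejection")
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        if rms > prev_rms + 1e-12:
            rises += 1
            if rises >= 5:
                raise RegistrationError(
                    f"ICP diverging: RMS rose 5 consecutive iterations "
                    f"(history tail {history[-6:]})"
                )
        else:
            rises = 0
        if abs(prev_rms - rms) < tol:
            return ICPResult(transform, rms, iteration, history)
        # re-fit the full transform from the original source points
        step = landmark_align(src[keep], closest[keep])
        transform = step
        prev_rms = rms
    return ICPResult(transform, prev_rms, max_iter, history)


@dataclass
class ChangeMap:
    """Per-vertex signed distance of the registered target surface from the
    reference surface; positive = target outside the reference (growth)."""

    values: np.ndarray  # (n target vertices,) mm
    target_mesh: SurfaceMesh  # target in the reference frame
    reference_id: str = ""
    target_id: str = ""
    transform_used: Optional[RigidTransform] = None

    def median(self) -> float:
        return float(np.median(self.values))


def change_map(
    reference: SurfaceMesh,
    target: SurfaceMesh,
    transform: Optional[RigidTransform] = None,
    reference_id: str = "",
    target_id: str = "",
) -> ChangeMap:
    """Signed minimum distance from each registered target vertex to the
    reference surface.

    Distances are point-to-triangle (not point-to-vertex); the sign comes
    from the outward reference normal at the closest point, so growth is
    positive and shrinkage negative.
    """
    transform = RigidTransform.identity() if transform is None else transform
    moved = transform.apply(target.vertices)
    ref_tm = reference.to_trimesh()
    query = MeshDistanceQuery(ref_tm)
    closest, dist, tid = query.query(moved)
    normals = ref_tm.face_normals[tid]
    offset = moved - closest
    sign = np.sign(np.einsum("ij,ij->i", offset, normals))
    sign[sign == 0] = 1.0
    values = dist * sign
    moved_mesh = SurfaceMesh(moved, target.faces.copy())
    moved_mesh.boundary_loops = [list(l) for l in target.boundary_loops]
    return ChangeMap(
        values=values,
        target_mesh=moved_mesh,
        reference_id=reference_id,
        target_id=target_id,
        transform_used=transform,
    )
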