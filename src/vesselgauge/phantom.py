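"""Parametric aorta-like phantoms with exact analytic ground truth.

The phantom family emulates the thoracic-aorta phenotypes the measurement
pipeline is designed for — a "candy cane" of straight ascending limb,
semicircular arch and straight descending limb, with circular or elliptical
cross-sections, an optional Gaussian coarctation (localized narrowing), an
optional localized dilation patch, and short branch stubs on the arch used
to exercise branch-exclusion logic.  Because every surface point comes from
a closed-form radius function, centerline position, tortuosity, arch
curvature, per-station maximum diameter and cross-sectional area are all
known exactly; the phantoms therefore stand in for patient imaging as the
test bed for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import (
    parallel_transport_frames,
    polyline_arc_length,
    voxelize_interior,
)
from .mesh_core import SurfaceMesh

__all__ = [
    "Coarctation",
    "DilationPatch",
    "BranchStub",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_open_phantom",
    "voxelize",
    "preset",
    "PRESETS",
]


@dataclass
class Coarctation:
    """Gaussian narrowing: radius is scaled by 1 - depth*exp(-(s-c)^2/2w^2)."""

    center_s: float  # arc length of the throat, mm
    depth: float  # fractional narrowing in (0, 1); 0.5 halves the radius
    width: float  # Gaussian sigma, mm


@dataclass
class DilationPatch:
    """Localized outward bulge of given amplitude (mm) over a Gaussian span.

    ``angular_width`` (radians) confines the bulge to a wedge of the
    circumference centred on ``angular_center``; ``None`` dilates the full
    circumference (radius grows by the amplitude on every axis).
    """

    center_s: float
    amplitude: float
    width: float
    angular_center: float = 0.0
    angular_width: Optional[float] = None


@dataclass
class BranchStub:
    """Short side cylinder on the arch outer wall (branch ostium surrogate)."""

    arc_length: float
    radius: float
    length: float


@dataclass
class PhantomSpec:
    """Geometry recipe for one phantom.

    ``arch_radius=None`` degenerates to a straight tube of length
    ``ascending_length + descending_length`` along +z.  ``tube_radius`` may
    be a scalar (mm) or a callable of arc length.  ``section_eccentricity``
    is the major/minor axis ratio (>= 1); the minor semi-axis equals the
    tube radius.  Defaults approximate an adult thoracic aorta.
    """

    arch_radius: Optional[float] = 40.0
    ascending_length: float = 70.0
    descending_length: float = 120.0
    tube_radius: float | Callable[[np.ndarray], np.ndarray] = 12.5
    section_eccentricity: float = 1.0
    coarctation: Optional[Coarctation] = None
    dilation_patch: Optional[DilationPatch] = None
    branch_stubs: Sequence[BranchStub] = field(default_factory=tuple)
    mesh_resolution: tuple = (200, 64)
    seed: int = 0

    def __post_init__(self):
        if self.ascending_length < 0 or self.descending_length < 0:
            raise ValueError("limb lengths must be >= 0")
        if self.arch_radius is not None and self.arch_radius <= 0:
            raise ValueError("arch_radius must be positive (or None for a tube)")
        if self.section_eccentricity < 1:
            raise ValueError("section_eccentricity is major/minor, must be >= 1")
        if self.coarctation is not None and not (0 < self.coarctation.depth < 1):
            raise ValueError("coarctation depth must be in (0, 1)")
        if self.mesh_resolution[1] < 16:
            raise ValueError("circumferential resolution must be >= 16")

    # -- analytic centerline ---------------------------------------------
    @property
    def total_length(self) -> float:
        if self.arch_radius is None:
            return self.ascending_length + self.descending_length
        return (
            self.ascending_length
            + np.pi * self.arch_radius
            + self.descending_length
        )

    def centerline_point(self, s: np.ndarray) -> np.ndarray:
        """Analytic centerline position at arc length ``s`` (vectorized)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.arch_radius is None:
            out = np.zeros((len(s), 3))
            out[:, 2] = s
            return out
        R, La = self.arch_radius, self.ascending_length
        arch_len = np.pi * R
        out = np.empty((len(s), 3))
        asc = s <= La
        out[asc] = np.column_stack(
            [np.full(asc.sum(), R), np.zeros(asc.sum()), s[asc] - La]
        )
        mid = (s > La) & (s < La + arch_len)
        theta = (s[mid] - La) / R
        out[mid] = np.column_stack(
            [R * np.cos(theta), np.zeros(mid.sum()), R * np.sin(theta)]
        )
        dsc = s >= La + arch_len
        out[dsc] = np.column_stack(
            [
                np.full(dsc.sum(), -R),
                np.zeros(dsc.sum()),
                -(s[dsc] - La - arch_len),
            ]
        )
        return out

    # -- analytic cross-section ------------------------------------------
    def base_radius(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        r = (
            self.tube_radius(s)
            if callable(self.tube_radius)
            else np.full_like(s, float(self.tube_radius), dtype=float)
        )
        if self.coarctation is not None:
            c = self.coarctation
            r = r * (1.0 - c.depth * np.exp(-0.5 * ((s - c.center_s) / c.width) ** 2))
        return r

    def section_radius(self, s, phi) -> np.ndarray:
        """Polar radius of the cross-section at arc length s, angle phi.

        phi is measured in the section frame from the major axis.
        Broadcasts s against phi.
        """
        s = np.asarray(s, dtype=float)
        phi = np.asarray(phi, dtype=float)
        b = self.base_radius(s)
        a = b * self.section_eccentricity
        rho = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        if self.dilation_patch is not None:
            d = self.dilation_patch
            axial = d.amplitude * np.exp(-0.5 * ((s - d.center_s) / d.width) ** 2)
            if d.angular_width is None:
                ang = 1.0
            else:
                dphi = np.angle(np.exp(1j * (phi - d.angular_center)))
                ang = np.exp(-0.5 * (dphi / d.angular_width) ** 2)
            rho = rho + axial * ang
        return rho


@dataclass
class GroundTruth:
    """Closed-form reference values evaluated on a dense arc-length grid."""

    s: np.ndarray  # mm, dense grid over [0, total_length]
    centerline_points: np.ndarray  # (n, 3)
    max_diameter: np.ndarray  # mm per station
    area: np.ndarray  # mm^2 per station
    min_radius: np.ndarray  # mm per station
    tortuosity: float
    apex_curvature: float  # 1/mm (0 for a straight tube)
    apex_s: Optional[float]  # arc length of the arch apex
    total_length: float

    def diameter_at(self, s) -> np.ndarray:
        return np.interp(s, self.s, self.max_diameter)

    def area_at(self, s) -> np.ndarray:
        return np.interp(s, self.s, self.area)


def _ground_truth(spec: PhantomSpec, ds: float = 0.25, n_phi: int = 720) -> GroundTruth:
    s = np.linspace(0.0, spec.total_length, int(np.ceil(spec.total_length / ds)) + 1)
    pts = spec.centerline_point(s)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    rho = spec.section_radius(s[:, None], phi[None, :])
    half = n_phi // 2
    chords = rho[:, :half] + rho[:, half:]
    max_diameter = chords.max(axis=1)
    area = 0.5 * (rho**2).sum(axis=1) * (2 * np.pi / n_phi)
    min_radius = rho.min(axis=1)
    chord = np.linalg.norm(pts[-1] - pts[0])
    if chord <= 0:
        raise ValueError("degenerate centerline (coincident endpoints)")
    tortuosity = float(spec.total_length / chord)
    if spec.arch_radius is None:
        apex_curv, apex_s = 0.0, None
    else:
        apex_curv = 1.0 / spec.arch_radius
        apex_s = spec.ascending_length + 0.5 * np.pi * spec.arch_radius
    return GroundTruth(
        s=s,
        centerline_points=pts,
        max_diameter=max_diameter,
        area=area,
        min_radius=min_radius,
        tortuosity=tortuosity,
        apex_curvature=apex_curv,
        apex_s=apex_s,
        total_length=spec.total_length,
    )


# ---------------------------------------------------------------------------
# mesh synthesis
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Build the watertight phantom surface and its analytic ground truth.

    Cross-section rings are placed on rotation-minimizing (parallel
    transport) frames along the analytic centerline, so the ellipse
    orientation does not twist around the arch.  Flat caps close the inlet
    and outlet; clip them off to obtain open rims.
    """
    truth = _ground_truth(spec)
    max_rho = float(
        spec.section_radius(
            truth.s[:, None], np.linspace(0, 2 * np.pi, 64)[None, :]
        ).max()
    )
    if spec.arch_radius is not None and max_rho >= spec.arch_radius:
        raise ValueError(
            f"tube radius {max_rho:.1f} mm >= arch radius {spec.arch_radius:.1f} mm: "
            "phantom would self-intersect"
        )

    n_ax, n_circ = spec.mesh_resolution
    s = np.linspace(0.0, spec.total_length, n_ax + 1)
    centers = spec.centerline_point(s)
    _, e1, e2 = parallel_transport_frames(centers)
    phi = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    rho = spec.section_radius(s[:, None], phi[None, :])  # (n_ax+1, n_circ)
    rings = (
        centers[:, None, :]
        + rho[:, :, None]
        * (np.cos(phi)[None, :, None] * e1[:, None, :] + np.sin(phi)[None, :, None] * e2[:, None, :])
    )
    vertices = rings.reshape(-1, 3)

    faces = []
    for i in range(n_ax):
        base0, base1 = i * n_circ, (i + 1) * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([base0 + j, base1 + j, base1 + j1])
            faces.append([base0 + j, base1 + j1, base0 + j1])
    # caps: fans around the centerline endpoints
    i_start_center = len(vertices)
    vertices = np.vstack([vertices, centers[0], centers[-1]])
    i_end_center = i_start_center + 1
    last = n_ax * n_circ
    for j in range(n_circ):
        j1 = (j + 1) % n_circ
        faces.append([i_start_center, j1, j])  # inlet cap, outward = -tangent
        faces.append([i_end_center, last + j, last + j1])
    faces = np.asarray(faces, dtype=np.int64)

    tm_vertices, tm_faces = vertices, faces
    mesh = SurfaceMesh.from_arrays(tm_vertices, tm_faces)
    if mesh.to_trimesh().volume < 0:
        mesh = SurfaceMesh.from_arrays(tm_vertices, tm_faces[:, ::-1])

    if spec.branch_stubs:
        mesh = _attach_stubs(mesh, spec)
    return mesh, truth


def make_open_phantom(spec: PhantomSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Phantom with the end caps removed, leaving open inlet/outlet rims.

    This is the shape the measurement pipeline normally receives (clinical
    surfaces are clipped at the inlet and outlet).  A half-space clip cannot
    open a candy cane — the limbs are parallel, so a transverse inlet plane
    would also cut the descending limb — hence the flat cap faces are
    deleted directly.  Ground truth is unchanged.
    """
    mesh, truth = make_phantom(spec)
    v, f = mesh.vertices, mesh.faces
    keep = np.ones(len(f), dtype=bool)
    for s_end in (0.0, spec.total_length):
        p = spec.centerline_point(np.array([s_end]))[0]
        d = np.linalg.norm(v - p, axis=1)
        center = int(np.argmin(d))
        if d[center] > 1e-6:
            raise RuntimeError("cap center vertex not found; was the mesh edited?")
        keep &= ~(f == center).any(axis=1)
    return SurfaceMesh.from_arrays(v, f[keep]), truth


def _stub_frame(spec: PhantomSpec, s_b: float):
    """Outward direction and surface radius at a stub attachment point."""
    ds = 0.5
    s_grid = np.arange(0.0, spec.total_length + ds / 2, ds)
    centers = spec.centerline_point(s_grid)
    _, e1, e2 = parallel_transport_frames(centers)
    i = int(np.argmin(np.abs(s_grid - s_b)))
    c = centers[i]
    if spec.arch_radius is None:
        direction = e1[i]
    else:
        radial = c - np.array([0.0, 0.0, 0.0])
        radial[1] = 0.0
        nr = np.linalg.norm(radial)
        direction = radial / nr if nr > 1e-9 else e1[i]
    u, v = float(np.dot(direction, e1[i])), float(np.dot(direction, e2[i]))
    phi = np.arctan2(v, u)
    rho = float(spec.section_radius(np.array([s_b]), np.array([phi]))[0])
    return c, direction, rho


def _attach_stubs(mesh: SurfaceMesh, spec: PhantomSpec) -> SurfaceMesh:
    """Cut an ostium hole per stub and append an open stub tube.

    The composite stays edge-manifold but is not watertight at the junction;
    stubs exist to exercise open-contour branch exclusion, not to model
    supra-aortic anatomy.
    """
    v = mesh.vertices
    f = mesh.faces
    n_circ = 16
    extra_v, extra_f = [], []
    keep = np.ones(len(f), dtype=bool)
    for stub in spec.branch_stubs:
        c, d, rho = _stub_frame(spec, stub.arc_length)
        base = c + d * rho
        tip = c + d * (rho + stub.length)
        # remove wall faces whose centroid is inside the stub cylinder
        centroids = v[f].mean(axis=1)
        rel = centroids - c
        t = rel @ d
        radial = rel - np.outer(t, d)
        inside = (np.linalg.norm(radial, axis=1) < stub.radius) & (t > 0)
        keep &= ~inside
        # stub tube: base ring just inside the wall, cap at the tip
        u = np.cross(d, [0, 1, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(d, [1, 0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(d, u)
        phi = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
        ring_dirs = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * w
        base_ring = c + d * (rho * 0.9) + stub.radius * ring_dirs
        tip_ring = tip + stub.radius * ring_dirs
        i0 = len(v) + sum(len(b) for b in extra_v)
        extra_v.extend([base_ring, tip_ring, tip[None, :]])
        i_tip_center = i0 + 2 * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            extra_f.append([i0 + j, i0 + n_circ + j, i0 + n_circ + j1])
            extra_f.append([i0 + j, i0 + n_circ + j1, i0 + j1])
            extra_f.append([i_tip_center, i0 + n_circ + j, i0 + n_circ + j1])
    new_v = np.vstack([v] + extra_v)
    new_f = np.vstack([f[keep]] + [np.asarray(extra_f, dtype=np.int64)])
    return SurfaceMesh.from_arrays(new_v, new_f)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize(
    phantom,
    spacing: float = 1.0,
    lumen_gv: float = 475.0,
    background_gv: float = 100.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    margin: int = 3,
):
    """Rasterize a phantom (PhantomSpec or SurfaceMesh) onto a voxel grid.

    Voxels inside the lumen take ``lumen_gv``, outside ``background_gv``,
    plus optional seeded Gaussian noise — the default grey values mimic the
    bright-lumen contrast that threshold segmentation (window 310-640 GV)
    expects.  PhantomSpec inputs are tested analytically against the section
    radius formula; meshes are tested by slice rasterization.
    """
    from .voxel_segmentation import VoxelImage

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if isinstance(phantom, PhantomSpec):
        rmin = float(np.min(phantom.base_radius(np.array([0.0, phantom.total_length / 2]))))
        if spacing > rmin:
            import warnings

            warnings.warn(
                f"voxel spacing {spacing} mm coarser than tube radius {rmin:.1f} mm",
                stacklevel=2,
            )
        mask, origin = _voxelize_spec(phantom, spacing, margin)
    else:
        tm = phantom.to_trimesh() if isinstance(phantom, SurfaceMesh) else phantom
        mask, origin = voxelize_interior(tm, spacing, margin=margin)
    values = np.where(mask, lumen_gv, background_gv).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return VoxelImage(values=values, spacing=(spacing,) * 3, origin=tuple(origin))


def _voxelize_spec(spec: PhantomSpec, spacing: float, margin: int):
    ds = min(0.25, spacing / 2)
    s_grid = np.arange(0.0, spec.total_length + ds / 2, ds)
    centers = spec.centerline_point(s_grid)
    tangents, e1, e2 = parallel_transport_frames(centers)
    rho_max = float(
        spec.section_radius(s_grid[:, None], np.linspace(0, 2 * np.pi, 64)[None, :]).max()
    )
    lo = centers.min(axis=0) - rho_max
    hi = centers.max(axis=0) + rho_max
    origin = lo - (margin - 0.5) * spacing
    counts = np.ceil((hi - lo) / spacing).astype(int) + 2 * margin
    ax = [origin[i] + spacing * np.arange(counts[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    tree = cKDTree(centers)
    _, idx = tree.query(pts, workers=-1)
    rel = pts - centers[idx]
    u = np.einsum("ij,ij->i", rel, e1[idx])
    v = np.einsum("ij,ij->i", rel, e2[idx])
    w = np.einsum("ij,ij->i", rel, tangents[idx])
    phi = np.arctan2(v, u)
    rho = spec.section_radius(s_grid[idx], phi)
    radial = np.sqrt(u * u + v * v)
    inside = radial <= rho
    # trim beyond the end caps
    at_start = idx == 0
    at_end = idx == len(s_grid) - 1
    inside &= ~(at_start & (w < 0))
    inside &= ~(at_end & (w > 0))
    return inside.reshape(X.shape), origin


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, **overrides) -> PhantomSpec:
    """Named phantom recipes used throughout the tests and examples."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return PhantomSpec(**params)


PRESETS = {
    # straight tube, adult-aorta caliber: the simplest analytic check
    "cylinder": dict(
        arch_radius=None,
        ascending_length=50.0,
        descending_length=50.0,
        tube_radius=12.5,
    ),
    # pure semicircular arch: tortuosity pi/2, apex curvature 1/R
    "arch": dict(
        arch_radius=40.0,
        ascending_length=0.0,
        descending_length=0.0,
        tube_radius=10.0,
    ),
    # full candy cane, circular sections
    "aorta": dict(),
    # juxtaductal-style narrowing halving the 24 mm base diameter
    "coarctation": dict(
        arch_radius=40.0,
        ascending_length=70.0,
        descending_length=120.0,
        tube_radius=12.0,
        coarctation=Coarctation(center_s=230.0, depth=0.5, width=8.0),
    ),
    # ascending dilation reminiscent of a dilated ascending aorta
    "dilation": dict(
        dilation_patch=DilationPatch(center_s=35.0, amplitude=3.0, width=10.0),
    ),
    # elongated transverse arch: longer, flatter arch with elliptical sections
    "eta": dict(
        arch_radius=50.0,
        ascending_length=60.0,
        descending_length=110.0,
        tube_radius=11.0,
        section_eccentricity=1.2,
    ),
    # arch with three supra-aortic branch stubs for exclusion tests
    "branched": dict(
        arch_radius=40.0,
        ascending_length=70.0,
        descending_length=120.0,
        branch_stubs=(
            BranchStub(arc_length=90.0, radius=4.0, length=12.0),
            BranchStub(arc_length=105.0, radius=3.5, length=12.0),
            BranchStub(arc_length=120.0, radius=3.5, length=12.0),
        ),
    ),
}
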