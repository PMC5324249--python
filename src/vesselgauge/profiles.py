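"""Continuous cross-sectional measurement along the centerline.

Planes are sampled every 2 mm normal to the (smoothed) centerline; at each
station the lumen contour is extracted, and the maximum diameter (largest
point-pair distance of the contour) and cross-sectional area are recorded.
Stations whose contour is open (rim or branch ostium) or that fall inside a
declared branch window are flagged excluded rather than dropped, mirroring
how branch ostia are shaded out of continuous diameter plots.  Profiles
from different visits can be aligned by a shared landmark and classified
into growth/shrinkage/stable per station.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geometry import plane_basis, plane_section_polylines
from .centerline import Centerline
from .mesh_core import SurfaceMesh

__all__ = [
    "CrossSection",
    "ProfileTable",
    "StationSet",
    "sample_planes",
    "section_contour",
    "contour_metrics",
    "measure_profile",
    "map_stations",
    "align_profiles",
    "classify_change",
    "DEFAULT_PLANE_SPACING",
    "DEFAULT_GROWTH_THRESHOLD",
]

DEFAULT_PLANE_SPACING = 2.0  # mm between measurement planes
# visit-to-visit diameter change below this is within inter-observer
# variability (about one pixel) and is reported as stable
DEFAULT_GROWTH_THRESHOLD = 1.5  # mm


@dataclass
class CrossSection:
    """One measurement station: plane, contour and scalar metrics."""

    station_arc_length: float
    plane_point: np.ndarray
    plane_normal: np.ndarray
    contour: Optional[np.ndarray] = None  # (n, 2) closed planar polygon, mm
    max_diameter: float = np.nan
    area: float = np.nan
    excluded: bool = False
    reason: str = ""


@dataclass
class ProfileTable:
    """Ordered per-station measurements at uniform arc-length spacing."""

    stations: list
    spacing: float
    provenance: dict = field(default_factory=dict)

    @property
    def s(self) -> np.ndarray:
        return np.array([c.station_arc_length for c in self.stations])

    @property
    def max_diameter(self) -> np.ndarray:
        """Max diameter per station, NaN where excluded."""
        return np.array(
            [np.nan if c.excluded else c.max_diameter for c in self.stations]
        )

    @property
    def area(self) -> np.ndarray:
        return np.array([np.nan if c.excluded else c.area for c in self.stations])

    @property
    def excluded(self) -> np.ndarray:
        return np.array([c.excluded for c in self.stations])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "s_mm": self.s,
                "max_diameter_mm": [c.max_diameter for c in self.stations],
                "area_mm2": [c.area for c in self.stations],
                "excluded": self.excluded,
                "reason": [c.reason for c in self.stations],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, what: str = "max_diameter_mm"):
        """Continuous line plot of diameter or area vs arc length, with
        excluded spans shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame()
        values = frame[what].to_numpy(dtype=float)
        values[self.excluded] = np.nan
        ax.plot(self.s, values, lw=1.5)
        for c in self.stations:
            if c.excluded:
                ax.axvspan(
                    c.station_arc_length - self.spacing / 2,
                    c.station_arc_length + self.spacing / 2,
                    color="0.2",
                    alpha=0.25,
                    lw=0,
                )
        ax.set_xlabel("arc length s (mm)")
        ax.set_ylabel(what.replace("_", " "))
        return ax


# the eight manual measurement stations, inlet to outlet
STATION_NAMES = (
    "sinotubular_junction",
    "mid_ascending",
    "proximal_arch",
    "mid_arch",
    "distal_arch",
    "isthmus",
    "mid_descending",
    "descending_at_left_atrium",
)


@dataclass
class StationSet:
    """Eight named landmark positions given as centerline arc lengths (mm).

    Anatomical landmark detection is deliberately out of scope: positions
    must be supplied (or picked) by the user in arc-length coordinates.
    """

    positions: dict

    def __post_init__(self):
        if tuple(self.positions) != STATION_NAMES:
            missing = set(STATION_NAMES) - set(self.positions)
            extra = set(self.positions) - set(STATION_NAMES)
            if missing or extra:
                raise ValueError(
                    f"station names must be exactly {STATION_NAMES}; "
                    f"missing {sorted(missing)}, unexpected {sorted(extra)}"
                )
            self.positions = {k: self.positions[k] for k in STATION_NAMES}
        values = list(self.positions.values())
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("station positions must be strictly increasing")

    @classmethod
    def evenly_spaced(cls, length: float, start: float = 0.05, end: float = 0.95):
        """Eight stations spread uniformly over a fraction of the centerline."""
        s = np.linspace(start * length, end * length, len(STATION_NAMES))
        return cls(dict(zip(STATION_NAMES, s)))


# ---------------------------------------------------------------------------
# plane sampling and contouring
# ---------------------------------------------------------------------------

def sample_planes(cl: Centerline, spacing: float = DEFAULT_PLANE_SPACING):
    """Measurement planes at s = 0, spacing, 2*spacing, ... along the
    centerline; each plane is normal to the local tangent.

    Returns a list of (point, unit normal) pairs.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > cl.length:
        raise ValueError(
            f"spacing {spacing} mm exceeds centerline length {cl.length:.1f} mm"
        )
    s_values = np.arange(0.0, cl.length + 1e-9, spacing)
    points = cl.point_at(s_values)
    normals = cl.tangent_at(s_values)
    return [(points[i], normals[i]) for i in range(len(s_values))]


def section_contour(
    mesh: SurfaceMesh, plane, center_point, station_arc_length: float = np.nan
) -> CrossSection:
    """Lumen contour cut by one plane.

    The mesh/plane intersection may contain several loops (a plane through
    the arch cuts both limbs); the loop enclosing — or failing that, nearest
    to — ``center_point`` is kept and projected to 2D plane coordinates.
    If that loop is open (the plane crossed a rim or a branch ostium) the
    station is flagged excluded with reason "open contour".
    """
    from shapely.geometry import Point, Polygon

    point, normal = plane
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    tm = mesh.to_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    polylines = plane_section_polylines(tm, point, normal)
    cs = CrossSection(
        station_arc_length=float(station_arc_length),
        plane_point=point,
        plane_normal=normal,
    )
    if not polylines:
        cs.excluded, cs.reason = True, "no intersection"
        return cs

    u, v = plane_basis(normal)
    c2 = np.array([center_point @ u, center_point @ v])
    best = None
    best_d = np.inf
    best_closed = False
    for loop in polylines:
        closed = len(loop) >= 4 and np.allclose(loop[0], loop[-1])
        loop2 = np.column_stack([loop @ u, loop @ v])
        if closed:
            poly = Polygon(loop2)
            if not poly.is_valid or poly.area <= 0:
                continue
            d = (
                0.0
                if poly.contains(Point(c2))
                else poly.exterior.distance(Point(c2))
            )
        else:
            d = float(np.linalg.norm(loop2 - c2, axis=1).min())
        # prefer enclosing/nearest; a closed loop beats an open one at a tie
        if d < best_d - 1e-9 or (abs(d - best_d) <= 1e-9 and closed and not best_closed):
            best, best_d, best_closed = loop2, d, closed
    if best is None:
        cs.excluded, cs.reason = True, "no usable contour"
        return cs
    if not best_closed:
        cs.excluded, cs.reason = True, "open contour"
        cs.contour = best
        return cs
    cs.contour = best if np.allclose(best[0], best[-1]) else np.vstack([best, best[:1]])
    try:
        cs.max_diameter, cs.area = contour_metrics(cs.contour)
    except ValueError as exc:
        cs.excluded, cs.reason = True, str(exc)
    return cs


def contour_metrics(contour: np.ndarray) -> tuple[float, float]:
    """(max diameter, area) of a simple closed planar polygon.

    Max diameter is the largest pairwise vertex distance (the polygon
    diameter, computed on the convex hull); area is the shoelace magnitude.
    Raises on self-intersecting input.
    """
    from shapely.geometry import Polygon
    from scipy.spatial import ConvexHull

    contour = np.asarray(contour, dtype=float)
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 distinct vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("self-intersecting contour")
    area = float(poly.area)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    max_diameter = float(np.sqrt((diff**2).sum(axis=2)).max())
    return max_diameter, area


# ---------------------------------------------------------------------------
# profile measurement
# ---------------------------------------------------------------------------

def measure_profile(
    mesh: SurfaceMesh,
    cl: Centerline,
    spacing: float = DEFAULT_PLANE_SPACING,
    branch_windows: Sequence[tuple] = (),
    area_jump_fraction: float = 0.30,
) -> ProfileTable:
    """Measure every station along the centerline.

    Exclusion is never an error: a station is flagged when (a) its contour
    is open, (b) its arc length falls in a user branch window, or (c) its
    area jumps by more than ``area_jump_fraction`` against both neighbours
    (automatic ostium detection).
    """
    planes = sample_planes(cl, spacing)
    s_values = np.arange(0.0, cl.length + 1e-9, spacing)
    stations = []
    for s, (point, normal) in zip(s_values, planes):
        cs = section_contour(mesh, (point, normal), point, station_arc_length=s)
        for lo, hi in branch_windows:
            if lo <= s <= hi and not cs.excluded:
                cs.excluded, cs.reason = True, "branch window"
        stations.append(cs)

    # automatic exclusion: area jumping against both neighbours
    areas = np.array([c.area for c in stations])
    for i in range(1, len(stations) - 1):
        c = stations[i]
        if c.excluded or not np.isfinite(areas[i]):
            continue
        prev_a, next_a = areas[i - 1], areas[i + 1]
        if not (np.isfinite(prev_a) and np.isfinite(next_a)):
            continue
        jump_prev = abs(areas[i] - prev_a) / prev_a
        jump_next = abs(areas[i] - next_a) / next_a
        if jump_prev > area_jump_fraction and jump_next > area_jump_fraction:
            c.excluded, c.reason = True, "area jump"

    return ProfileTable(
        stations=stations,
        spacing=float(spacing),
        provenance={"n_vertices": len(mesh.vertices), "n_points": len(cl.points)},
    )


def map_stations(profile: ProfileTable, stations: StationSet) -> dict:
    """Diameter at each named landmark, from the nearest non-excluded station.

    Returns {name: (arc_length_used, diameter, warned)}; ``warned`` is True
    when the landmark fell on an excluded station and a neighbour was used.
    """
    s = profile.s
    diam = profile.max_diameter
    out = {}
    for name, target in stations.positions.items():
        if target < s[0] - profile.spacing or target > s[-1] + profile.spacing:
            raise ValueError(f"landmark {name} at {target} mm outside profile range")
        order = np.argsort(np.abs(s - target))
        nearest = order[0]
        warned = False
        idx = next((i for i in order if np.isfinite(diam[i])), None)
        if idx is None:
            raise ValueError("profile has no usable stations")
        if idx != nearest:
            warned = True
            warnings.warn(
                f"landmark {name} falls on an excluded station; using the "
                f"nearest measured station at s={s[idx]:.1f} mm",
                stacklevel=2,
            )
        out[name] = (float(s[idx]), float(diam[idx]), warned)
    return out


# ---------------------------------------------------------------------------
# visit alignment and change classification
# ---------------------------------------------------------------------------

def align_profiles(
    a: ProfileTable, b: ProfileTable, landmark_a: float, landmark_b: float
) -> ProfileTable:
    """Shift profile ``b`` so its landmark coincides with ``a``'s, and
    resample it onto ``a``'s stations by linear interpolation.

    The alignment is a single rigid arc-length shift (visits are aligned at
    one shared branch landmark); stations of ``a`` outside the shifted range
    of ``b`` come back excluded ("out of range").
    """
    shift = landmark_a - landmark_b
    sb = b.s + shift
    if sb[-1] < a.s[0] or sb[0] > a.s[-1]:
        raise ValueError("profiles do not overlap after landmark alignment")

    def interp(values):
        good = np.isfinite(values)
        return np.interp(a.s, sb[good], values[good], left=np.nan, right=np.nan)

    diam = interp(b.max_diameter)
    area = interp(b.area)
    in_range = (a.s >= sb[0] - 1e-9) & (a.s <= sb[-1] + 1e-9)
    # stations of b that were excluded poison the aligned stations they cover
    excluded_spans = [
        (s - b.spacing / 2 + shift, s + b.spacing / 2 + shift)
        for s, exc in zip(b.s, b.excluded)
        if exc
    ]
    stations = []
    for i, s in enumerate(a.s):
        cs = CrossSection(
            station_arc_length=float(s),
            plane_point=a.stations[i].plane_point,
            plane_normal=a.stations[i].plane_normal,
            max_diameter=float(diam[i]),
            area=float(area[i]),
        )
        if not in_range[i]:
            cs.excluded, cs.reason = True, "out of range"
        elif any(lo <= s <= hi for lo, hi in excluded_spans) or not np.isfinite(
            diam[i]
        ):
            cs.excluded, cs.reason = True, "excluded in source profile"
        stations.append(cs)
    return ProfileTable(
        stations=stations,
        spacing=a.spacing,
        provenance={"aligned_from": b.provenance, "shift_mm": shift},
    )


def classify_change(
    a: ProfileTable,
    b: ProfileTable,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> np.ndarray:
    """Per-station growth/shrinkage/stable labels for two aligned profiles.

    Growth when the diameter increased by more than ``threshold`` mm (the
    inter-observer variability floor), shrinkage when it decreased by more,
    stable otherwise; exclusions propagate as "excluded".
    """
    if len(a.stations) != len(b.stations) or not np.allclose(a.s, b.s):
        raise ValueError("profiles must share stations; align them first")
    da, db = a.max_diameter, b.max_diameter
    labels = np.full(len(da), "stable", dtype=object)
    change = db - da
    labels[change > threshold] = "growth"
    labels[change < -threshold] = "shrinkage"
    labels[~np.isfinite(change)] = "excluded"
    return labels
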