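"""Plane sampling, contour metrics, profiles, alignment, change labels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

import vesselgauge as vg
from vesselgauge.profiles import STATION_NAMES


class TestSamplePlanes:
    def test_station_count_on_100mm_centerline(self, cylinder_case):
        planes = vg.sample_planes(cylinder_case.centerline, spacing=2.0)
        assert len(planes) == 51

    def test_normals_equal_tangents(self, arch_case):
        cl = arch_case.centerline
        planes = vg.sample_planes(cl, spacing=2.0)
        s = np.arange(0, cl.length + 1e-9, 2.0)
        tangents = cl.tangent_at(s)
        dots = [float(n @ t) for (_, n), t in zip(planes, tangents)]
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)

    def test_spacing_larger_than_length_rejected(self, cylinder_case):
        with pytest.raises(ValueError):
            vg.sample_planes(cylinder_case.centerline, spacing=500.0)


class TestSectionContour:
    def test_cylinder_transverse_cut(self, cylinder_case):
        cs = vg.section_contour(
            cylinder_case.mesh, ([0, 0, 50.0], [0, 0, 1.0]), np.array([0, 0, 50.0])
        )
        assert not cs.excluded
        r = np.linalg.norm(cs.contour - cs.contour.mean(axis=0), axis=1)
        assert np.abs(r - 12.5).max() < 0.2

    def test_plane_through_both_limbs_picks_enclosing(self, coarctation_case):
        from shapely.geometry import Point, Polygon

        spec = coarctation_case.spec
        # horizontal plane below the arch cuts ascending and descending limbs
        center = spec.centerline_point(np.array([30.0]))[0]  # on ascending limb
        cs = vg.section_contour(
            coarctation_case.mesh, (center, [0, 0, 1.0]), center
        )
        assert not cs.excluded
        poly = Polygon(cs.contour)
        # projected center (plane basis maps x,y -> in-plane coords) is inside
        from vesselgauge._geometry import plane_basis

        u, v = plane_basis(np.array([0.0, 0, 1.0]))
        assert poly.contains(Point([center @ u, center @ v]))
        # and it is the ascending limb: radius ~12, not the far descending cut
        assert poly.area == pytest.approx(np.pi * 12.0**2, rel=0.05)

    def test_branch_ostium_gives_open_contour(self, branched_case):
        spec = branched_case.spec
        stub = spec.branch_stubs[0]
        center = spec.centerline_point(np.array([stub.arc_length]))[0]
        normal = branched_case.centerline.tangent_at(np.array([stub.arc_length]))[0]
        cs = vg.section_contour(branched_case.mesh, (center, normal), center)
        assert cs.excluded
        assert cs.reason == "open contour"


class TestContourMetrics:
    def test_circle_limits(self):
        t = np.linspace(0, 2 * np.pi, 361)
        contour = 12.5 * np.column_stack([np.cos(t), np.sin(t)])
        d, a = vg.contour_metrics(contour)
        assert d == pytest.approx(25.0, rel=1e-4)
        assert a == pytest.approx(np.pi * 12.5**2, rel=1e-4)

    def test_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 361)
        contour = np.column_stack([15 * np.cos(t), 10 * np.sin(t)])
        d, a = vg.contour_metrics(contour)
        assert d == pytest.approx(30.0, rel=1e-4)
        assert a == pytest.approx(np.pi * 15 * 10, rel=1e-3)

    @given(st.integers(min_value=0, max_value=500))
    def test_convex_polygon_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 25))
        radii = rng.uniform(5, 15, 25)
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
        d, a = vg.contour_metrics(hull)
        diff = hull[:, None] - hull[None, :]
        brute_d = np.sqrt((diff**2).sum(axis=2)).max()
        x, y = hull[:, 0], hull[:, 1]
        brute_a = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert d == pytest.approx(brute_d, rel=1e-12)
        assert a == pytest.approx(brute_a, rel=1e-12)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            vg.contour_metrics(bowtie)


class TestMeasureProfile:
    def test_cylinder_uniform_diameter(self, cylinder_profile):
        prof = cylinder_profile
        interior = (prof.s > 5) & (prof.s < prof.s[-1] - 5)
        d = prof.max_diameter[interior]
        assert np.isfinite(d).all()
        assert np.abs(d / 25.0 - 1).max() < 0.005

    def test_coarctation_minimum_found(self, coarctation_case):
        prof = vg.measure_profile(coarctation_case.mesh, coarctation_case.centerline)
        d = prof.max_diameter
        body = (prof.s > 10) & (prof.s < prof.s[-1] - 10)
        idx = np.flatnonzero(body)[np.nanargmin(d[body])]
        assert d[idx] == pytest.approx(12.0, rel=0.03)
        assert prof.s[idx] == pytest.approx(230.0, abs=2.0)

    def test_branch_stubs_trigger_exclusions_only_near_stubs(self, branched_case):
        prof = vg.measure_profile(branched_case.mesh, branched_case.centerline)
        stub_s = [b.arc_length for b in branched_case.spec.branch_stubs]
        excluded_s = prof.s[prof.excluded]
        body = (prof.s > 4) & (prof.s < prof.s[-1] - 4)
        for s0 in stub_s:
            assert np.any(np.abs(excluded_s - s0) <= 6.0), f"no exclusion near {s0}"
        far = [
            s
            for s in excluded_s
            if min(abs(s - s0) for s0 in stub_s) > 10 and 4 < s < prof.s[-1] - 4
        ]
        assert far == []

    def test_manual_branch_windows_flagged(self, cylinder_case):
        prof = vg.measure_profile(
            cylinder_case.mesh, cylinder_case.centerline, branch_windows=[(40, 50)]
        )
        window = (prof.s >= 40) & (prof.s <= 50)
        assert prof.excluded[window].all()
        assert not prof.excluded[(prof.s > 5) & (prof.s < 35)].any()

    def test_area_and_diameter_trends_agree(self):
        # monotonically tapering tube: rank correlation between the two
        spec = vg.preset(
            "cylinder", tube_radius=lambda s: 14.0 - 0.04 * np.asarray(s)
        )
        mesh, truth = vg.make_open_phantom(spec)
        cl = vg.compute_centerline(
            mesh, truth.centerline_points[0], truth.centerline_points[-1]
        )
        prof = vg.measure_profile(mesh, cl)
        good = np.isfinite(prof.max_diameter) & np.isfinite(prof.area)
        rho = sstats.spearmanr(prof.max_diameter[good], prof.area[good]).statistic
        assert rho > 0.9

    def test_profile_invariant_under_rigid_motion(self, cylinder_case, rigid_motion):
        base = vg.measure_profile(cylinder_case.mesh, cylinder_case.centerline)
        moved_mesh = vg.SurfaceMesh(
            rigid_motion.apply(cylinder_case.mesh.vertices),
            cylinder_case.mesh.faces.copy(),
        )
        moved_mesh.boundary_loops = cylinder_case.mesh.boundary_loops
        src = rigid_motion.apply(cylinder_case.truth.centerline_points[[0]])[0]
        dst = rigid_motion.apply(cylinder_case.truth.centerline_points[[-1]])[0]
        cl = vg.compute_centerline(moved_mesh, src, dst)
        prof = vg.measure_profile(moved_mesh, cl)
        interior = (base.s > 5) & (base.s < base.s[-1] - 5)
        np.testing.assert_allclose(
            prof.max_diameter[interior], base.max_diameter[interior], atol=0.1
        )


class TestStations:
    def test_uniform_cylinder_all_stations_equal(self, cylinder_profile):
        stations = vg.StationSet.evenly_spaced(100.0, start=0.1, end=0.9)
        mapped = vg.map_stations(cylinder_profile, stations)
        assert set(mapped) == set(STATION_NAMES)
        for _, (s_used, diameter, warned) in mapped.items():
            assert diameter == pytest.approx(25.0, rel=0.005)
            assert not warned

    def test_landmark_snaps_to_nearer_station(self, cylinder_profile):
        stations = vg.StationSet.evenly_spaced(100.0)
        positions = dict(stations.positions)
        positions["mid_arch"] = 48.9  # stations at 48 and 50: nearer is 48
        mapped = vg.map_stations(cylinder_profile, vg.StationSet(positions))
        assert mapped["mid_arch"][0] == pytest.approx(48.0)

    def test_landmark_in_excluded_window_warns_and_uses_neighbor(self, cylinder_case):
        prof = vg.measure_profile(
            cylinder_case.mesh, cylinder_case.centerline, branch_windows=[(48, 56)]
        )
        stations = vg.StationSet.evenly_spaced(100.0)
        positions = dict(stations.positions)
        positions["mid_arch"] = 52.0
        with pytest.warns(UserWarning, match="excluded"):
            mapped = vg.map_stations(prof, vg.StationSet(positions))
        s_used = mapped["mid_arch"][0]
        assert s_used < 48 or s_used > 56
        assert np.isfinite(mapped["mid_arch"][1])

    def test_unordered_stations_rejected(self):
        stations = vg.StationSet.evenly_spaced(100.0)
        positions = dict(stations.positions)
        positions["mid_ascending"] = 99.0
        with pytest.raises(ValueError, match="increasing"):
            vg.StationSet(positions)


class TestAlignment:
    def test_zero_shift_is_identity(self, cylinder_profile):
        aligned = vg.align_profiles(cylinder_profile, cylinder_profile, 50.0, 50.0)
        good = ~aligned.excluded
        np.testing.assert_allclose(
            aligned.max_diameter[good],
            cylinder_profile.max_diameter[good],
            atol=1e-9,
        )

    def test_known_shift_recovered(self, cylinder_profile):
        a = cylinder_profile
        shifted = vg.align_profiles(a, a, landmark_a=56.0, landmark_b=50.0)
        # b's s=50 value now sits at a's s=56
        good = ~shifted.excluded & np.isfinite(a.max_diameter)
        resid = shifted.max_diameter[good] - a.max_diameter[good]
        assert np.abs(resid).max() < 0.1

    def test_non_overlapping_shift_rejected(self, cylinder_profile):
        with pytest.raises(ValueError, match="overlap"):
            vg.align_profiles(cylinder_profile, cylinder_profile, 500.0, 0.0)


class TestClassifyChange:
    def test_identical_profiles_all_stable(self, cylinder_profile):
        labels = vg.classify_change(cylinder_profile, cylinder_profile)
        good = ~cylinder_profile.excluded
        assert set(labels[good]) == {"stable"}

    def test_uniform_growth_above_threshold(self, cylinder_profile):
        import copy

        grown = copy.deepcopy(cylinder_profile)
        for c in grown.stations:
            c.max_diameter += 2.0
        labels = vg.classify_change(cylinder_profile, grown, threshold=1.5)
        good = ~cylinder_profile.excluded
        assert set(labels[good]) == {"growth"}

    def test_localized_dilation_labels_only_patch(self):
        base_spec = vg.preset("cylinder")
        dil_spec = vg.preset(
            "cylinder",
            dilation_patch=vg.DilationPatch(center_s=50.0, amplitude=1.5, width=8.0),
        )
        mesh_a, truth_a = vg.make_open_phantom(base_spec)
        mesh_b, truth_b = vg.make_open_phantom(dil_spec)
        cl_a = vg.compute_centerline(
            mesh_a, truth_a.centerline_points[0], truth_a.centerline_points[-1]
        )
        cl_b = vg.compute_centerline(
            mesh_b, truth_b.centerline_points[0], truth_b.centerline_points[-1]
        )
        pa = vg.measure_profile(mesh_a, cl_a)
        pb = vg.measure_profile(mesh_b, cl_b)
        aligned = vg.align_profiles(pa, pb, 50.0, 50.0)
        labels = vg.classify_change(pa, aligned, threshold=1.5)
        growth_s = pa.s[labels == "growth"]
        # +3 mm peak diameter increase, Gaussian width 8 mm: growth within the span
        assert len(growth_s) > 0
        assert np.all(np.abs(growth_s - 50.0) <= 12.0)
        far = labels[(np.abs(pa.s - 50.0) > 25) & ~pa.excluded & ~aligned.excluded]
        assert set(far) <= {"stable"}
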