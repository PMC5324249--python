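"""Euclidean distance field from surface to centerline."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import vesselgauge as vg
from vesselgauge.distance_map import _RESAMPLE_STEP


class TestEuclideanField:
    def test_cylinder_field_is_radius(self, cylinder_case):
        field = vg.euclidean_field(cylinder_case.mesh, cylinder_case.centerline)
        body = np.abs(cylinder_case.mesh.vertices[:, 2] - 50.0) < 45
        assert np.abs(field.distance[body] - 12.5).max() < 0.2
        assert (field.distance > 0).all()

    def test_elliptical_tube_spans_both_semiaxes(self):
        spec = vg.preset("cylinder", tube_radius=10.0, section_eccentricity=1.5)
        mesh, truth = vg.make_open_phantom(spec)
        cl = vg.compute_centerline(
            mesh, truth.centerline_points[0], truth.centerline_points[-1]
        )
        field = vg.euclidean_field(mesh, cl)
        body = np.abs(mesh.vertices[:, 2] - 50.0) < 40
        d = field.distance[body]
        assert d.min() == pytest.approx(10.0, abs=0.3)
        assert d.max() == pytest.approx(15.0, abs=0.3)

    def test_dilation_patch_raises_local_maximum(self):
        spec = vg.preset(
            "cylinder",
            dilation_patch=vg.DilationPatch(
                center_s=50.0, amplitude=2.0, width=8.0, angular_width=0.8
            ),
        )
        mesh, truth = vg.make_open_phantom(spec)
        # measure against the analytic spine: an extracted centerline would
        # itself lean toward the one-sided bulge (as a medial axis does)
        from vesselgauge._geometry import polyline_arc_length, polyline_tangents
        from vesselgauge.centerline import Centerline

        pts = truth.centerline_points
        cl = Centerline(
            pts,
            polyline_arc_length(pts),
            np.full(len(pts), 12.5),
            polyline_tangents(pts),
        )
        field = vg.euclidean_field(mesh, cl)
        patch = np.abs(field.station_s - 50.0) < 4
        assert field.distance[patch].max() == pytest.approx(12.5 + 2.0, abs=0.3)
        away = np.abs(field.station_s - 50.0) > 25
        body = away & (field.station_s > 5) & (field.station_s < 95)
        assert field.distance[body].max() < 12.8

    def test_matches_exhaustive_nearest_point(self, cylinder_case):
        # KD-tree query vs brute force over all dense centerline points
        mesh = cylinder_case.mesh
        assert len(mesh.vertices) <= 15000
        cl = cylinder_case.centerline
        field = vg.euclidean_field(mesh, cl)
        dense = cl.resampled(_RESAMPLE_STEP)
        brute = np.sqrt(
            (
                (mesh.vertices[:, None, :] - dense.points[None, :, :]) ** 2
            ).sum(axis=2)
        ).min(axis=1)
        np.testing.assert_array_equal(field.distance, brute)

    def test_rigid_invariance_and_scaling(self, cylinder_case, rigid_motion):
        from vesselgauge.centerline import Centerline
        from vesselgauge._geometry import polyline_tangents

        mesh, cl = cylinder_case.mesh, cylinder_case.centerline
        f0 = vg.euclidean_field(mesh, cl)
        moved_mesh = vg.SurfaceMesh(rigid_motion.apply(mesh.vertices), mesh.faces.copy())
        moved_cl = Centerline(
            rigid_motion.apply(cl.points),
            cl.arc_length,
            cl.inscribed_radius,
            polyline_tangents(rigid_motion.apply(cl.points)),
        )
        f1 = vg.euclidean_field(moved_mesh, moved_cl)
        np.testing.assert_allclose(f1.distance, f0.distance, atol=1e-9)
        k = 3.0
        scaled = vg.euclidean_field(
            vg.SurfaceMesh(mesh.vertices * k, mesh.faces.copy()),
            Centerline(cl.points * k, cl.arc_length * k, cl.inscribed_radius * k, cl.tangents),
        )
        np.testing.assert_allclose(scaled.distance, k * f0.distance, rtol=1e-9)

    def test_branched_centerlines_claim_stub_vertices(self, branched_case):
        # vertices on a stub are closer to the branch path than the main one
        spec = branched_case.spec
        cl_main = branched_case.centerline
        stub = spec.branch_stubs[0]
        from vesselgauge.phantom import _stub_frame

        c, d, rho = _stub_frame(spec, stub.arc_length)
        tip = c + d * (rho + stub.length)
        # synthetic straight branch path from the main line to the stub tip
        branch_pts = np.linspace(c, tip, 30)
        from vesselgauge._geometry import polyline_arc_length, polyline_tangents
        from vesselgauge.centerline import Centerline

        branch = Centerline(
            branch_pts,
            polyline_arc_length(branch_pts),
            np.full(30, stub.radius),
            polyline_tangents(branch_pts),
        )
        single = vg.euclidean_field(branched_case.mesh, cl_main)
        multi = vg.euclidean_field(branched_case.mesh, [cl_main, branch])
        near_tip = np.linalg.norm(branched_case.mesh.vertices - tip, axis=1) < stub.radius * 1.5
        assert near_tip.any()
        assert multi.distance[near_tip].max() < single.distance[near_tip].min()


class TestRegions:
    def test_uniform_cylinder_halves(self, cylinder_case):
        field = vg.euclidean_field(cylinder_case.mesh, cylinder_case.centerline)
        table = vg.summarize_regions(field, (50.0, 50.0))
        asc = table[table.region == "ascending"].iloc[0]
        dsc = table[table.region == "descending"].iloc[0]
        assert asc.mean_mm == pytest.approx(12.5, abs=0.2)
        assert dsc.mean_mm == pytest.approx(12.5, abs=0.2)
        assert table[table.region == "arch"].iloc[0].n_vertices == 0

    def test_distinct_region_calibers(self):
        spec = vg.preset(
            "cylinder",
            tube_radius=lambda s: np.where(np.asarray(s) < 50.0, 13.0, 10.0),
        )
        mesh, truth = vg.make_open_phantom(spec)
        cl = vg.compute_centerline(
            mesh, truth.centerline_points[0], truth.centerline_points[-1]
        )
        field = vg.euclidean_field(mesh, cl)
        table = vg.summarize_regions(field, (40.0, 60.0))
        asc = table[table.region == "ascending"].iloc[0]
        dsc = table[table.region == "descending"].iloc[0]
        assert asc.mean_mm == pytest.approx(13.0, abs=0.3)
        assert dsc.mean_mm == pytest.approx(10.0, abs=0.3)
        assert (table.max_mm.dropna() >= table.mean_mm.dropna() - 1e-12).all()

    def test_degenerate_cuts_report_zero_counts(self, cylinder_case):
        field = vg.euclidean_field(cylinder_case.mesh, cylinder_case.centerline)
        table = vg.summarize_regions(field, (1000.0, 2000.0))
        assert table[table.region == "ascending"].iloc[0].n_vertices == len(
            cylinder_case.mesh.vertices
        )
        assert table[table.region == "arch"].iloc[0].n_vertices == 0
        assert table[table.region == "descending"].iloc[0].n_vertices == 0


class TestAsymmetry:
    def test_circular_tube_is_symmetric(self, cylinder_case):
        field = vg.euclidean_field(cylinder_case.mesh, cylinder_case.centerline)
        s, idx = vg.asymmetry_index(field)
        body = (s > 5) & (s < 95)
        assert idx[body].max() < 0.02

    def test_elliptical_tube_index(self):
        spec = vg.preset("cylinder", tube_radius=10.0, section_eccentricity=1.5)
        mesh, truth = vg.make_open_phantom(spec)
        cl = vg.compute_centerline(
            mesh, truth.centerline_points[0], truth.centerline_points[-1]
        )
        field = vg.euclidean_field(mesh, cl)
        s, idx = vg.asymmetry_index(field)
        body = (s > 10) & (s < 90)
        # (a - b)/mean = 5 / 12.5 = 0.4
        assert np.median(idx[body]) == pytest.approx(0.4, rel=0.10)

    def test_index_invariant_under_rigid_motion(self, cylinder_case, rigid_motion):
        from vesselgauge._geometry import polyline_tangents
        from vesselgauge.centerline import Centerline

        mesh, cl = cylinder_case.mesh, cylinder_case.centerline
        f0 = vg.euclidean_field(mesh, cl)
        moved = vg.euclidean_field(
            vg.SurfaceMesh(rigid_motion.apply(mesh.vertices), mesh.faces.copy()),
            Centerline(
                rigid_motion.apply(cl.points),
                cl.arc_length,
                cl.inscribed_radius,
                polyline_tangents(rigid_motion.apply(cl.points)),
            ),
        )
        s0, i0 = vg.asymmetry_index(f0)
        s1, i1 = vg.asymmetry_index(moved)
        np.testing.assert_allclose(i0, i1, atol=1e-9)


def test_ply_export_reimports_with_scalars(tmp_path, cylinder_case):
    import trimesh

    field = vg.euclidean_field(cylinder_case.mesh, cylinder_case.centerline)
    path = tmp_path / "field.ply"
    vg.distance_map.write_ply(cylinder_case.mesh, field.distance, path)
    text = path.read_text()
    assert "euclid_mm" in text
    back = trimesh.load(str(path), process=False)
    assert len(back.vertices) == len(cylinder_case.mesh.vertices)
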