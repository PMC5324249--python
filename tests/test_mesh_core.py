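"""Surface container, STL dialects, Taubin smoothing, plane clipping."""

import numpy as np
import pytest
import trimesh

import vesselgauge as vg
from vesselgauge.mesh_core import MeshValidationError


def _cube_trimesh():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


class TestReadWriteSTL:
    def test_binary_cube_topology(self, tmp_path):
        path = tmp_path / "cube.stl"
        _cube_trimesh().export(path, file_type="stl")
        mesh = vg.read_stl(path)
        assert len(mesh.vertices) == 8
        assert len(mesh.faces) == 12
        assert mesh.is_closed

    def test_ascii_and_binary_dialects_agree(self, tmp_path):
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        cube = _cube_trimesh()
        cube.export(pa, file_type="stl_ascii")
        cube.export(pb, file_type="stl")
        ma, mb = vg.read_stl(pa), vg.read_stl(pb)
        # same vertex multiset up to ordering
        va = np.sort(np.round(ma.vertices, 9).view([("x", float), ("y", float), ("z", float)]), axis=0)
        vb = np.sort(np.round(mb.vertices, 9).view([("x", float), ("y", float), ("z", float)]), axis=0)
        assert (va == vb).all()
        assert len(ma.faces) == len(mb.faces)

    def test_write_read_roundtrip_exact(self, tmp_path):
        mesh, _ = vg.make_phantom(vg.preset("cylinder", mesh_resolution=(24, 16)))
        path = tmp_path / "tube.stl"
        vg.write_stl(mesh, path)
        back = vg.read_stl(path)
        key = lambda v: np.lexsort(v.T)
        np.testing.assert_array_equal(
            mesh.vertices[key(mesh.vertices)], back.vertices[key(back.vertices)]
        )
        # and a second write produces byte-identical output
        path2 = tmp_path / "tube2.stl"
        vg.write_stl(back, path2)
        vg.write_stl(vg.read_stl(path2), path)
        assert path.read_bytes() == path2.read_bytes()

    def test_malformed_and_empty_inputs_raise(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_bytes(b"solid nope\nthis is not a facet\nendsolid")
        with pytest.raises(MeshValidationError):
            vg.read_stl(bad)


class TestValidation:
    def test_degenerate_and_duplicate_faces_removed(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        f = np.array([[0, 1, 2], [0, 1, 2], [0, 0, 1], [0, 2, 3]])
        mesh = vg.SurfaceMesh.from_arrays(v, f)
        assert len(mesh.faces) == 2

    def test_nonmanifold_edge_rejected(self):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], dtype=float
        )
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
        with pytest.raises(MeshValidationError, match="non-manifold"):
            vg.SurfaceMesh.from_arrays(v, f)

    def test_boundary_loop_bookkeeping(self, cylinder_case):
        assert len(cylinder_case.mesh.boundary_loops) == 2
        closed, _ = vg.make_phantom(vg.preset("cylinder", mesh_resolution=(24, 16)))
        assert closed.is_closed


class TestSmoothing:
    def test_sphere_barely_moves_at_defaults(self):
        sphere = vg.SurfaceMesh.from_trimesh(trimesh.creation.icosphere(4, 10.0))
        out = vg.smooth_mesh(sphere)
        disp = np.linalg.norm(out.vertices - sphere.vertices, axis=1)
        assert disp.max() < 0.1

    def test_noise_attenuation_beats_smooth_surface_motion(self):
        # smoothing must act on noise, not just move everything a little
        sphere = vg.SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, 10.0))
        rng = np.random.default_rng(2)
        radial = sphere.vertices / np.linalg.norm(
            sphere.vertices, axis=1, keepdims=True
        )
        noisy = vg.SurfaceMesh(
            sphere.vertices + radial * rng.normal(0, 0.2, (len(sphere.vertices), 1)),
            sphere.faces.copy(),
        )
        out = vg.smooth_mesh(noisy)
        res_before = np.abs(np.linalg.norm(noisy.vertices, axis=1) - 10.0)
        res_after = np.abs(np.linalg.norm(out.vertices, axis=1) - 10.0)
        assert res_after.mean() < 0.5 * res_before.mean()

    def test_volume_preserved_within_one_percent(self):
        sphere = vg.SurfaceMesh.from_trimesh(trimesh.creation.icosphere(4, 10.0))
        out = vg.smooth_mesh(sphere)
        assert abs(out.volume() - sphere.volume()) / sphere.volume() < 0.01

    def test_zero_iterations_is_identity(self, cylinder_case):
        out = vg.smooth_mesh(cylinder_case.mesh, iterations=0)
        np.testing.assert_array_equal(out.vertices, cylinder_case.mesh.vertices)

    def test_noise_reduced_on_jittered_cylinder(self):
        mesh, _ = vg.make_phantom(vg.preset("cylinder", mesh_resolution=(120, 64)))
        rng = np.random.default_rng(5)
        normals = mesh.vertices.copy()
        normals[:, 2] = 0
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        radial = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
        noisy = vg.SurfaceMesh(
            mesh.vertices + radial * rng.normal(0, 0.3, size=(len(mesh.vertices), 1)),
            mesh.faces.copy(),
        )

        def radial_rms(m):
            body = np.abs(m.vertices[:, 2] - 50.0) < 40  # away from caps
            r = np.linalg.norm(m.vertices[body, :2], axis=1)
            return np.sqrt(np.mean((r - 12.5) ** 2))

        smoothed = vg.smooth_mesh(noisy, iterations=30, factor=0.5)
        assert radial_rms(smoothed) < radial_rms(noisy)

    @pytest.mark.parametrize("factor", [0.0, 1.0, -0.2, 1.5])
    def test_factor_out_of_range_rejected(self, cylinder_case, factor):
        with pytest.raises(ValueError):
            vg.smooth_mesh(cylinder_case.mesh, factor=factor)


class TestClipping:
    def test_cylinder_two_cuts_opens_tube(self):
        cyl = vg.SurfaceMesh.from_trimesh(
            trimesh.creation.cylinder(radius=10.0, height=60.0, sections=48)
        )
        planes = [
            vg.ClipPlane(point=[0, 0, -20.0], normal=[0, 0, 1.0]),
            vg.ClipPlane(point=[0, 0, 20.0], normal=[0, 0, -1.0]),
        ]
        out = vg.clip_mesh(cyl, planes)
        assert len(out.boundary_loops) == 2
        assert out.vertices[:, 2].min() >= -20.0 - 1e-6
        assert out.vertices[:, 2].max() <= 20.0 + 1e-6

    def test_cut_rim_lies_on_plane(self):
        sphere = vg.SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, 10.0))
        out = vg.clip_mesh(sphere, vg.ClipPlane(point=[0, 0, 0], normal=[0, 0, 1.0]))
        assert len(out.boundary_loops) == 1
        rim_z = out.vertices[out.boundary_loops[0], 2]
        assert np.abs(rim_z).max() < 1e-6

    def test_retained_lateral_area_matches_analytic(self):
        cyl = vg.SurfaceMesh.from_trimesh(
            trimesh.creation.cylinder(radius=10.0, height=60.0, sections=128)
        )
        planes = [
            vg.ClipPlane(point=[0, 0, -15.0], normal=[0, 0, 1.0]),
            vg.ClipPlane(point=[0, 0, 15.0], normal=[0, 0, -1.0]),
        ]
        out = vg.clip_mesh(cyl, planes)
        analytic = 2 * np.pi * 10.0 * 30.0
        assert abs(out.area() - analytic) / analytic < 0.01

    def test_plane_missing_mesh_warns_and_noops(self, cylinder_case):
        with pytest.warns(UserWarning, match="does not intersect"):
            out = vg.clip_mesh(
                cylinder_case.mesh,
                vg.ClipPlane(point=[0, 0, 500.0], normal=[0, 0, 1.0]),
            )
        assert len(out.faces) == len(cylinder_case.mesh.faces)

    def test_kept_halfspace_predicate(self):
        sphere = vg.SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, 10.0))
        plane = vg.ClipPlane(point=[1.0, 2.0, 3.0], normal=[1.0, 1.0, 0.0])
        out = vg.clip_mesh(sphere, plane)
        assert plane.signed_distance(out.vertices).min() > -1e-6
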