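import numpy as np
import pytest

from femaxes.creation import box, cylinder, icosphere, torus
from femaxes.errors import MeshError, MeshIOError
from femaxes.mesh import SurfaceMesh, mass_properties, merge_meshes, signed_volume
from femaxes.meshfile import load_mesh, save_mesh
from femaxes.sections import (Ball, HalfSpace, cap_plane_boundary, clip_mesh,
                              cut_mesh_with_plane, intersect_line_mesh,
                              silhouette)
from femaxes.transforms import Line3, Plane3, random_rigid_transform


class TestIO:
    def test_unit_cube_stl(self, tmp_path):
        p = tmp_path / "cube.stl"
        save_mesh(box((1, 1, 1)), str(p))
        m = load_mesh(str(p))
        assert m.n_vertices == 8 and m.n_faces == 12
        assert m.is_closed

    def test_open_cube(self):
        b = box()
        m = SurfaceMesh(b.vertices, b.faces[:-1], clean=False)
        assert not m.is_closed

    def test_femur_ply_roundtrip_identity(self, tmp_path, default_case):
        _, mesh, _ = default_case
        p = tmp_path / "femur.ply"
        save_mesh(mesh, str(p))
        m2 = load_mesh(str(p))
        assert m2.n_vertices == mesh.n_vertices
        assert m2.n_faces == mesh.n_faces

    @pytest.mark.parametrize("fmt,binary", [("stl", False), ("stl", True),
                                            ("ply", False), ("ply", True),
                                            ("obj", False)])
    def test_format_roundtrips(self, tmp_path, fmt, binary):
        m = icosphere(3.0, (1, -2, 0.5), 2)
        p = tmp_path / f"s.{fmt}"
        save_mesh(m, str(p), binary=binary)
        m2 = load_mesh(str(p))
        assert m2.n_vertices == m.n_vertices
        assert m2.is_closed
        tol = 1e-5 if fmt == "stl" else 1e-9  # STL stores float32
        assert mass_properties(m2)[0] == pytest.approx(mass_properties(m)[0],
                                                       rel=tol * 100 + 1e-12)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshIOError):
            load_mesh(str(tmp_path / "nope.stl"))

    def test_empty_mesh_rejected(self, tmp_path):
        p = tmp_path / "empty.obj"
        p.write_text("# nothing\n")
        with pytest.raises(MeshIOError):
            load_mesh(str(p))


class TestMassProperties:
    def test_unit_cube_analytic(self):
        V, com, inertia = mass_properties(box((1, 1, 1)))
        assert V == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(com, 0.0, atol=1e-12)
        # analytic box inertia: m(b^2+c^2)/12 = 1/6 per axis
        assert np.allclose(inertia, np.eye(3) / 6.0, atol=1e-12)

    def test_box_analytic_general(self):
        a, b, c = 4.0, 2.0, 1.0
        V, com, inertia = mass_properties(box((a, b, c), center=(3, -1, 2)))
        m = a * b * c
        assert V == pytest.approx(m, rel=1e-12)
        assert np.allclose(com, [3, -1, 2], atol=1e-9)
        expected = m / 12.0 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        assert np.allclose(inertia, expected, atol=1e-9)

    def test_sphere_volume_converges(self):
        r = 2.5
        prev_err = None
        for sub in (2, 3, 4):
            V, _, _ = mass_properties(icosphere(r, subdivisions=sub))
            err = abs(V - 4.0 / 3.0 * np.pi * r ** 3)
            if prev_err is not None:
                assert err < prev_err
            prev_err = err
        assert err / (4.0 / 3.0 * np.pi * r ** 3) < 0.005

    def test_cylinder_within_half_percent(self):
        V, _, _ = mass_properties(cylinder(1.0, 2.0, sections=128))
        assert abs(V - 2 * np.pi) / (2 * np.pi) < 0.005

    def test_translation_equivariance(self):
        _, com0, I0 = mass_properties(box((2, 3, 4)))
        t = np.array([10.0, -20.0, 5.0])
        _, com1, I1 = mass_properties(box((2, 3, 4), center=t))
        assert np.allclose(com1 - com0, t, atol=1e-9)
        assert np.allclose(I0, I1, atol=1e-9)

    def test_open_mesh_rejected(self):
        b = box()
        open_mesh = SurfaceMesh(b.vertices, b.faces[:-1], clean=False)
        with pytest.raises(MeshError):
            mass_properties(open_mesh)


class TestCut:
    def test_cylinder_circle_perimeter(self):
        c = cylinder(3.0, 10.0, sections=256)
        contours = cut_mesh_with_plane(c, Plane3((0, 0, 0), (0, 0, 1)))
        assert len(contours) == 1
        assert contours[0].closed
        assert contours[0].perimeter == pytest.approx(2 * np.pi * 3.0, rel=2e-4)
        assert contours[0].area == pytest.approx(np.pi * 9.0, rel=4e-4)

    def test_plane_outside_bbox(self):
        c = cylinder(1.0, 2.0)
        assert cut_mesh_with_plane(c, Plane3((0, 0, 100), (0, 0, 1))) == []

    def test_torus_two_components(self):
        t = torus(2.0, 0.5)
        contours = cut_mesh_with_plane(t, Plane3((0, 0, 0), (1, 0, 0)))
        assert len(contours) == 2
        # brute-force edge-crossing oracle: crossing edges = 2 * total contour pts
        d = t.vertices[:, 0]
        e = t.edges_unique()
        n_cross = int(((d[e[:, 0]] < 0) != (d[e[:, 1]] < 0)).sum())
        assert sum(len(c.points) for c in contours) == n_cross

    def test_contours_exactly_planar(self, default_case):
        _, mesh, _ = default_case
        plane = Plane3((0, 0, 0), (1, 0, 0))
        for c in cut_mesh_with_plane(mesh, plane):
            assert c.max_plane_distance() < 1e-6


class TestClip:
    def test_half_cube_volume(self):
        half = clip_mesh(box((1, 1, 1)), HalfSpace(Plane3((0, 0, 0), (1, 0, 0))))
        # re-close with a cap on the cut plane and take the exact volume
        closed = cap_plane_boundary(half, Plane3((0, 0, 0), (1, 0, 0)))
        assert closed.is_closed
        assert mass_properties(closed)[0] == pytest.approx(0.5, abs=1e-9)
        # divergence-theorem shortcut with the apex on the cut plane
        assert signed_volume(half, origin=(0, 0, 0)) == pytest.approx(0.5, abs=1e-9)

    def test_ball_larger_than_mesh_is_identity(self):
        s = icosphere(1.0, subdivisions=2)
        out = clip_mesh(s, Ball((0, 0, 0), 50.0))
        assert out.n_vertices == s.n_vertices

    def test_clip_removing_everything_raises(self):
        with pytest.raises(MeshError):
            clip_mesh(box(), HalfSpace(Plane3((10, 0, 0), (1, 0, 0))))

    def test_femur_middle_half_extent(self, default_case):
        _, mesh, _ = default_case
        d = np.array([1.0, 0.0, 0.0])
        s = mesh.vertices @ d
        lo, hi = s.min(), s.max()
        quarter = (hi - lo) / 4.0
        m = clip_mesh(mesh, HalfSpace(Plane3((lo + quarter, 0, 0), d)))
        m = clip_mesh(m, HalfSpace(Plane3((hi - quarter, 0, 0), -d)))
        # faces split exactly at the clip planes: extent = half the original
        assert m.extent_along(d) == pytest.approx((hi - lo) / 2.0, abs=1e-6)

    def test_ball_clip_boundary_exact(self):
        s = icosphere(2.0, subdivisions=3)
        out = clip_mesh(s, Ball((2.0, 0.0, 0.0), 1.0))
        # kept region: points of the sphere within the ball -> x >= 1.75
        # (edge-split points lie on chords of the tessellated sphere, so
        # allow the discretization sagitta)
        assert out.vertices[:, 0].min() >= 1.75 - 0.02


class TestSilhouette:
    def test_sphere_circle_area(self):
        s = icosphere(2.0, subdivisions=4)
        sil = silhouette(s, (0, 0, 1))
        assert len(sil) == 1
        assert sil[0].area == pytest.approx(np.pi * 4.0, rel=0.005)

    def test_cube_unit_square(self):
        sil = silhouette(box((1, 1, 1)), (0, 0, 1))
        assert len(sil) == 1
        assert sil[0].area == pytest.approx(1.0, abs=1e-9)

    def test_two_disjoint_spheres(self):
        two = merge_meshes([icosphere(1.0, (0, 0, 0), 3), icosphere(1.0, (5, 0, 0), 3)])
        sil = silhouette(two, (0, 0, 1))
        assert len(sil) == 2
        for c in sil:
            # projected-convex-hull oracle per component: a disc of radius 1
            assert c.area == pytest.approx(np.pi, rel=0.01)

    def test_degenerate_view_raises(self):
        flat = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]], clean=False)
        with pytest.raises(MeshError):
            silhouette(flat, (1, 0, 0))


class TestLineMesh:
    def test_sphere_two_hits(self):
        s = icosphere(2.0, (1, 0, 0), 3)
        pts, ts = intersect_line_mesh(s, Line3((0, 0, 0), (1, 0, 0)))
        assert len(ts) == 2
        assert pts[0][0] == pytest.approx(-1.0, abs=0.01)
        assert pts[1][0] == pytest.approx(3.0, abs=0.01)


class TestRigidEquivariance:
    def test_cut_clip_silhouette_equivariant(self):
        rng = np.random.default_rng(11)
        T = random_rigid_transform(rng, max_angle_deg=180, max_translation=100)
        mesh = cylinder(2.0, 6.0, sections=64)
        plane = Plane3((0, 0, 0.5), (0.2, 0.1, 1.0) / np.linalg.norm([0.2, 0.1, 1.0]))
        base = cut_mesh_with_plane(mesh, plane)
        moved = cut_mesh_with_plane(mesh.transformed(T), plane.transformed(T))
        assert len(base) == len(moved)
        assert moved[0].perimeter == pytest.approx(base[0].perimeter, abs=1e-9)
        assert moved[0].area == pytest.approx(base[0].area, abs=1e-9)
        # clip: volumes agree after transport
        clip_base = clip_mesh(mesh, HalfSpace(plane))
        clip_moved = clip_mesh(mesh.transformed(T), HalfSpace(plane.transformed(T)))
        assert clip_moved.area() == pytest.approx(clip_base.area(), abs=1e-9)
        # mass properties transform correctly
        V0, com0, _ = mass_properties(mesh)
        V1, com1, _ = mass_properties(mesh.transformed(T))
        assert V1 == pytest.approx(V0, abs=1e-9)
        assert np.allclose(com1, T.apply(com0), atol=1e-9)
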