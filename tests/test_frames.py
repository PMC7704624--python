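import numpy as np
import pytest

from femaxes.errors import FemaxesError
from femaxes.frames import (BoneFrame, FrameDifference, build_bergmann2016,
                            build_tabletop, build_wu2002, frame_difference,
                            recompose_difference, robustness_check)
from femaxes.transforms import (Line3, RigidTransform, random_rigid_transform,
                                rotation_about_axis, unit)

from conftest import angle_deg


def assert_frame_valid(f: BoneFrame):
    assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-9)


class TestWu2002:
    def test_hand_computed_example(self):
        f = build_wu2002(fhc=[0, 0, 400], mec=[-40, 0, 0], lec=[40, 0, 0],
                         side="right")
        assert_frame_valid(f)
        assert np.allclose(f.dp, [0, 0, 1], atol=1e-12)   # mechanical axis
        assert np.allclose(np.abs(f.ml), [1, 0, 0], atol=1e-12)
        assert np.allclose(np.abs(f.pa), [0, 1, 0], atol=1e-12)
        assert np.allclose(f.origin, [0, 0, 400])

    def test_degenerate_epicondyles(self):
        with pytest.raises(FemaxesError):
            build_wu2002([0, 0, 400], [1, 2, 3], [1, 2, 3], "right")

    def test_equivariance(self):
        rng = np.random.default_rng(5)
        T = random_rigid_transform(rng)
        args = ([0, 5, 400], [-40, -3, 2], [41, 2, -1])
        f0 = build_wu2002(*args, side="right")
        f1 = build_wu2002(*(T.apply(a) for a in args), side="right")
        assert np.allclose(f1.axes, f0.axes @ T.rotation.T, atol=1e-9)
        assert np.allclose(f1.origin, T.apply(f0.origin), atol=1e-9)


class TestBergmann2016:
    def test_mutual_perpendicular_oracle(self):
        neck = Line3([0, 50, 380], [0, 1, 0])
        shaft = Line3([0, 0, 0], [0, 0, 1])
        f = build_bergmann2016(fhc=[10, 40, 390], mpc=[-30, 0, 5], lpc=[30, 0, 5],
                               icn=[0, 0, -10], neck_axis=neck, shaft_axis=shaft,
                               side="right")
        assert_frame_valid(f)
        # P* = (0, 0, 380): straight axis from ICN (0,0,-10) -> +z
        assert np.allclose(f.dp, [0, 0, 1], atol=1e-12)

    def test_intersecting_axes(self):
        neck = Line3([0, 0, 100], unit([0, 1, 1]))
        shaft = Line3([0, 0, 0], [0, 0, 1])
        f = build_bergmann2016([5, 30, 120], [-30, 0, 0], [30, 0, 0], [0, 0, -10],
                               neck, shaft, "right")
        assert_frame_valid(f)

    def test_parallel_axes_raise(self):
        with pytest.raises(FemaxesError):
            build_bergmann2016([0, 0, 0], [-30, 0, 0], [30, 0, 0], [0, 0, -10],
                               Line3([0, 1, 0], [0, 0, 1]),
                               Line3([0, 0, 0], [0, 0, 1]), "right")

    def test_synthetic_straight_axis(self, varied_result, varied_case):
        _, _, gt = varied_case
        f = varied_result.frames["Bergmann2016"]
        assert_frame_valid(f)
        # straight femur axis roughly follows the shaft direction
        assert angle_deg(f.dp, gt.axes["shaft"].direction) < 10.0


class TestTableTop:
    def test_hand_computed_example(self):
        f = build_tabletop(fhc=[0, 0, 400], mpc=[-30, 0, 0], lpc=[30, 0, 0],
                           ttp_normal=[0, 1, 0], side="right")
        assert_frame_valid(f)
        assert np.allclose(f.pa, [0, 1, 0], atol=1e-12)
        assert np.allclose(np.abs(f.ml), [1, 0, 0], atol=1e-12)
        assert np.allclose(np.abs(f.dp), [0, 0, 1], atol=1e-12)

    def test_non_orthogonal_inputs_still_orthonormal(self):
        # realistic: condylar axis not exactly orthogonal to the TTP normal
        f = build_tabletop([3, 10, 395], [-31, -2, 1], [29, 3, -2],
                           unit([0.05, 0.99, 0.1]), "right")
        assert_frame_valid(f)
        # 2nd axis (TTP normal) kept exact
        assert abs(abs(f.pa @ unit([0.05, 0.99, 0.1])) - 1.0) < 1e-12

    def test_parallel_inputs_raise(self):
        with pytest.raises(FemaxesError):
            build_tabletop([0, 0, 400], [-30, 0, 0], [30, 0, 0], [1, 0, 0], "right")


class TestSideConventions:
    def test_mirrored_pair_conventions(self, mirrored_pair):
        (mesh_r, gt_r, res_r), (mesh_l, gt_l, res_l) = mirrored_pair
        for name in ("Wu2002", "Bergmann2016", "TableTop"):
            fr, fl = res_r.frames[name], res_l.frames[name]
            assert_frame_valid(fr)
            assert_frame_valid(fl)
            for f, gt in ((fr, gt_r), (fl, gt_l)):
                prox = gt.axes["shaft"].direction
                anterior = -gt.planes["TTP"].normal
                # PA anterior-positive, DP proximal-positive on both sides
                assert f.pa @ anterior > 0.7, (name, gt.side)
                assert f.dp @ prox > 0.7, (name, gt.side)
            # ML lateral-positive on the right, medial-positive on the left
            # (a single right-handed triad cannot be lateral on both sides)
            lateral_r = unit(gt_r.landmarks["LEC"] - gt_r.landmarks["MEC"])
            lateral_l = unit(gt_l.landmarks["LEC"] - gt_l.landmarks["MEC"])
            assert fr.ml @ lateral_r > 0.7, name
            assert fl.ml @ lateral_l < -0.7, name

    def test_invalid_side(self):
        with pytest.raises(FemaxesError):
            build_wu2002([0, 0, 400], [-40, 0, 0], [40, 0, 0], "sinister")


class TestFrameDifference:
    def _frame(self, R=np.eye(3)):
        axes = np.stack([R @ np.array([1.0, 0, 0]), R @ np.array([0, 1.0, 0]),
                         R @ np.array([0, 0, 1.0])])
        return BoneFrame("Wu2002", np.zeros(3), axes)

    def test_identical_frames_zero(self):
        f = self._frame()
        d = frame_difference(f, f)
        assert d.as_array() == pytest.approx([0, 0, 0], abs=1e-12)

    def test_rotation_about_reference_pa_is_aa(self):
        ref = self._frame()
        R = rotation_about_axis(ref.pa, 5.0)
        test = BoneFrame("Wu2002", np.zeros(3), ref.axes @ R.T)
        d = frame_difference(ref, test)
        assert d.adduction_abduction == pytest.approx(5.0, abs=1e-9)
        assert d.internal_external == pytest.approx(0.0, abs=1e-9)
        assert d.flexion_extension == pytest.approx(0.0, abs=1e-9)

    def test_roundtrip_recomposition(self):
        rng = np.random.default_rng(0)
        ref = self._frame()
        T = random_rigid_transform(rng, max_angle_deg=40, max_translation=0)
        test = BoneFrame("Wu2002", np.zeros(3), ref.axes @ T.rotation.T)
        d = frame_difference(ref, test)
        from femaxes.frames import _comparison_matrix
        R = _comparison_matrix(ref) @ _comparison_matrix(test).T
        assert np.allclose(recompose_difference(d), R, atol=1e-12)

    def test_small_angle_antisymmetry(self):
        ref = self._frame()
        # antisymmetry is exact only to second order in the angle
        for angle, tol in ((0.01, 2e-6), (4.0, 0.2)):
            R = rotation_about_axis([0.3, 0.5, 1.0], angle)
            test = BoneFrame("Wu2002", np.zeros(3), ref.axes @ R.T)
            d1 = frame_difference(ref, test).as_array()
            d2 = frame_difference(test, ref).as_array()
            assert np.allclose(d1, -d2, atol=tol)

    def test_name_mismatch(self):
        with pytest.raises(FemaxesError):
            frame_difference(self._frame(),
                             BoneFrame("TableTop", np.zeros(3), np.eye(3)))


class TestRobustnessHarness:
    def test_identity_transform_zero_discrepancy(self, default_case, template):
        _, mesh, _ = default_case
        report = robustness_check(mesh, "right", template=template,
                                  n_transforms=1, seed=0,
                                  max_angle_deg=0.0, max_translation=0.0)
        assert report["n_ok"] == 1
        assert report["max_landmark_discrepancy_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_report(self, default_case, template):
        _, mesh, _ = default_case
        r1 = robustness_check(mesh, "right", template=template, n_transforms=1, seed=7)
        r2 = robustness_check(mesh, "right", template=template, n_transforms=1, seed=7)
        assert r1 == r2

    def test_invalid_n(self, default_case, template):
        _, mesh, _ = default_case
        with pytest.raises(FemaxesError):
            robustness_check(mesh, "right", template=template, n_transforms=0)
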