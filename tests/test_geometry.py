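"""Forward/inverse projective landmark maps and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from fluoropose import (
    ImageLandmarks,
    LandmarkPlacement,
    Pose,
    ProjectionGeometry,
    estimate_depth,
    estimate_projection_angle,
    fit_leg_line,
    landmarks_from_pose,
    pose_from_landmarks,
)
from fluoropose.geometry import (
    DegenerateLegError,
    GeometryError,
    InvalidLandmarksError,
    wrap_angle,
)

from conftest import random_pose


class TestPoseType:
    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError, match="depth"):
            Pose(x=0, y=0, alpha=0, tau=0, d=0.0)

    def test_alpha_normalized_to_half_open_interval(self):
        assert Pose(0, 0, alpha=270.0, tau=0, d=1).alpha == -90.0
        assert Pose(0, 0, alpha=-180.0, tau=0, d=1).alpha == 180.0

    def test_tau_bounds(self):
        with pytest.raises(ValueError, match="tau"):
            Pose(0, 0, alpha=0, tau=91.0, d=1)


class TestPlacement:
    def test_default_cross_layout(self, placement):
        # 3+1 landmarks on the axis leg, 2+1 on the normal leg, shared center
        assert len(placement) == 6
        assert len(placement.x_leg) == 4
        assert len(placement.y_leg) == 3
        x_off = np.sort(placement.offsets[placement.x_leg, 0])
        y_off = np.sort(placement.offsets[placement.y_leg, 1])
        assert np.all(np.diff(x_off) == 15.0)
        assert np.all(np.diff(y_off) == 15.0)

    def test_rejects_two_centers(self):
        with pytest.raises(ValueError, match="central"):
            LandmarkPlacement(offsets=[[0, 0], [0, 0], [15, 0]])

    def test_rejects_diagonal_offset(self):
        with pytest.raises(ValueError, match="nonzero"):
            LandmarkPlacement(offsets=[[0, 0], [15, 15]])


class TestForwardMap:
    @pytest.mark.parametrize(
        "pose_kw, offset, expected",
        [
            # 2 px/mm magnification: +15 mm axial offset lands 30 px right
            (dict(x=100, y=100, alpha=0, tau=0, d=1000), (15, 0), (130, 100)),
            # rotating alpha by 90 deg maps the offset toward +y (down)
            (dict(x=100, y=100, alpha=90, tau=0, d=1000), (15, 0), (100, 130)),
            # normal-leg offsets are unaffected by tau
            (dict(x=100, y=100, alpha=0, tau=60, d=1000), (0, 15), (100, 130)),
        ],
    )
    def test_single_offset_projection(self, geom, pose_kw, offset, expected):
        placement = LandmarkPlacement(offsets=[[0, 0], list(offset)])
        pts = landmarks_from_pose(Pose(**pose_kw), geom, placement).points
        assert pts[1] == pytest.approx(expected, abs=1e-9)

    def test_edge_on_view_collapses_axis_leg(self, geom, placement):
        pts = landmarks_from_pose(Pose(100, 100, 0, 90, 1000), geom, placement).points
        assert np.allclose(pts[placement.x_leg], [100.0, 100.0], atol=1e-9)

    def test_translation_equivariance(self, geom, placement):
        rng = np.random.default_rng(3)
        pose = random_pose(rng, geom)
        base = landmarks_from_pose(pose, geom, placement).points
        moved = landmarks_from_pose(
            Pose(pose.x + 7.5, pose.y - 3.25, pose.alpha, pose.tau, pose.d),
            geom, placement).points
        assert np.allclose(moved - base, [7.5, -3.25], atol=1e-9)

    def test_rotation_equivariance(self, geom, placement):
        rng = np.random.default_rng(4)
        pose = random_pose(rng, geom)
        delta = 37.0
        base = landmarks_from_pose(pose, geom, placement).points
        rot = landmarks_from_pose(
            Pose(pose.x, pose.y, pose.alpha + delta, pose.tau, pose.d),
            geom, placement).points
        a = math.radians(delta)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        center = np.array([pose.x, pose.y])
        assert np.allclose(rot, (base - center) @ R.T + center, atol=1e-8)

    def test_magnification_scales_inverse_with_depth(self, geom, placement):
        pose = Pose(500, 500, 20, 30, 800)
        double = Pose(500, 500, 20, 30, 1600)
        s1 = landmarks_from_pose(pose, geom, placement).points - [500, 500]
        s2 = landmarks_from_pose(double, geom, placement).points - [500, 500]
        assert np.allclose(s1, 2.0 * s2, atol=1e-9)


class TestLegLineFit:
    def test_collinear_horizontal(self):
        c, d = fit_leg_line(np.array([[0, 0], [1, 0], [2, 0]]), offsets=[0, 1, 2])
        assert c == pytest.approx([1, 0])
        assert d == pytest.approx([1, 0])

    def test_two_points_vertical(self):
        c, d = fit_leg_line(np.array([[0, 0], [0, 2]]), offsets=[0, 1])
        assert c == pytest.approx([0, 1])
        assert d == pytest.approx([0, 1])

    def test_noisy_fit_close_to_true_direction(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4, 5)
        true_dir = np.array([math.cos(0.3), math.sin(0.3)])
        pts = np.outer(t, true_dir) + rng.normal(0, 0.01, size=(5, 2))
        _, d = fit_leg_line(pts, offsets=t)
        angle = math.degrees(math.acos(np.clip(abs(d @ true_dir), 0, 1)))
        assert angle < 1.0

    def test_orientation_follows_offset_order(self):
        c, d = fit_leg_line(np.array([[5, 0], [3, 0], [1, 0]]), offsets=[-1, 0, 1])
        assert d[0] < 0  # most-positive offset sits at the smallest x

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateLegError):
            fit_leg_line(np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]))


class TestDepthAndProjectionAngle:
    def test_depth_from_normal_leg_spacing(self, geom):
        placement = LandmarkPlacement(offsets=[[0, 0], [0, -15], [0, 15], [15, 0]])
        pts = ImageLandmarks(points=[[100, 100], [100, 70], [100, 130], [130, 100]])
        # 30 mm spacing over 60 px at c_d2p = 5e-4 -> 1000 mm
        assert estimate_depth(pts, placement, geom) == pytest.approx(1000.0)

    def test_depth_inverse_proportional_to_image_spread(self, geom, placement):
        pose = Pose(500, 500, 10, 20, 1000)
        pts = landmarks_from_pose(pose, geom, placement).points
        center = np.array([pose.x, pose.y])
        halved = ImageLandmarks(points=center + 0.5 * (pts - center))
        d = estimate_depth(ImageLandmarks(points=pts), placement, geom)
        d_half = estimate_depth(halved, placement, geom)
        assert d_half == pytest.approx(2.0 * d, rel=1e-12)

    def test_coincident_pair_rejected(self, geom):
        placement = LandmarkPlacement(offsets=[[0, 0], [0, 15], [15, 0]])
        pts = ImageLandmarks(points=[[100, 100], [100, 100], [130, 100]])
        with pytest.raises(InvalidLandmarksError):
            estimate_depth(pts, placement, geom)

    def test_projection_angle_cosine(self, geom):
        placement = LandmarkPlacement(offsets=[[0, 0], [30, 0], [0, 15]])
        # 30 mm pair projecting to 51.96 px with c_d2p * d = 0.5
        pts = ImageLandmarks(points=[[100, 100], [100 + 51.9615242, 100], [100, 130]])
        tau, clamped = estimate_projection_angle(pts, placement, geom, d=1000.0)
        assert tau == pytest.approx(30.0, abs=1e-5)
        assert not clamped

    def test_face_on_view_gives_zero_and_clamps(self, geom):
        placement = LandmarkPlacement(offsets=[[0, 0], [30, 0], [0, 15]])
        pts = ImageLandmarks(points=[[100, 100], [160, 100], [100, 130]])
        tau, _ = estimate_projection_angle(pts, placement, geom, d=1000.0)
        assert tau == pytest.approx(0.0, abs=1e-9)
        # slightly longer leg than geometrically possible -> clamped
        pts2 = ImageLandmarks(points=[[100, 100], [160.5, 100], [100, 130]])
        tau2, clamped = estimate_projection_angle(pts2, placement, geom, d=1000.0)
        assert tau2 == 0.0
        assert clamped


class TestInverseMap:
    def test_exact_inversion_of_reference_example(self, geom, placement):
        pose = Pose(100, 100, 0, 0, 1000)
        rec, diags = pose_from_landmarks(
            landmarks_from_pose(pose, geom, placement), placement, geom)
        assert (rec.x, rec.y) == pytest.approx((100, 100), abs=1e-9)
        assert rec.alpha == pytest.approx(0, abs=1e-9)
        assert rec.tau == pytest.approx(0, abs=1e-4)
        assert rec.d == pytest.approx(1000, rel=1e-9)
        assert not diags.cos_tau_clamped

    def test_round_trip_over_random_poses(self, geom, placement):
        rng = np.random.default_rng(12)
        for _ in range(2000):
            pose = random_pose(rng, geom)
            rec, _ = pose_from_landmarks(
                landmarks_from_pose(pose, geom, placement), placement, geom)
            assert abs(rec.x - pose.x) < 1e-6
            assert abs(rec.y - pose.y) < 1e-6
            assert abs(wrap_angle(rec.alpha - pose.alpha)) < 1e-6
            assert abs(rec.d - pose.d) / pose.d < 1e-6
            assert abs(rec.tau - abs(pose.tau)) < 1e-4

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x=st.floats(100, 900),
        y=st.floats(100, 900),
        alpha=st.floats(-180, 180),
        tau=st.floats(-80, 80),
        d=st.floats(850, 950),
    )
    def test_round_trip_property(self, geom, placement, x, y, alpha, tau, d):
        """Inversion reproduces any pose with |tau| <= 80 deg."""
        pose = Pose(x=x, y=y, alpha=alpha, tau=tau, d=d)
        rec, _ = pose_from_landmarks(
            landmarks_from_pose(pose, geom, placement), placement, geom)
        assert abs(rec.x - pose.x) < 1e-6
        assert abs(rec.y - pose.y) < 1e-6
        assert abs(wrap_angle(rec.alpha - pose.alpha)) < 1e-6
        assert abs(rec.d - pose.d) / pose.d < 1e-6
        assert abs(rec.tau - abs(pose.tau)) < 1e-4

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(deg=st.floats(-1e6, 1e6, allow_nan=False))
    def test_wrap_angle_range_and_equivalence(self, deg):
        wrapped = wrap_angle(deg)
        assert -180.0 < wrapped <= 180.0
        # wrapped and original differ by a multiple of 360 degrees
        assert abs((deg - wrapped) % 360.0) % 360.0 < 1e-6

    def test_edge_on_landmarks_fail_loudly(self, geom, placement):
        lm = landmarks_from_pose(Pose(100, 100, 0, 90, 1000), geom, placement)
        with pytest.raises(GeometryError):
            pose_from_landmarks(lm, placement, geom)

    def test_noisy_inversion_matches_nonlinear_least_squares(self, geom, placement):
        """The geometric inversion tracks a full nonlinear refit of the
        projection model under small landmark noise."""
        rng = np.random.default_rng(42)
        pose = Pose(100, 100, 0, 0, 1000)
        clean = landmarks_from_pose(pose, geom, placement).points

        def model(theta):
            p = Pose(x=theta[0], y=theta[1], alpha=theta[2],
                     tau=min(max(theta[3], -90.0), 90.0), d=max(theta[4], 1.0))
            return landmarks_from_pose(p, geom, placement).points.ravel()

        pos_err, alpha_err = [], []
        for _ in range(20):
            noisy = clean + rng.normal(0, 0.1, size=clean.shape)
            rec, _ = pose_from_landmarks(
                ImageLandmarks(points=noisy), placement, geom)
            sol = least_squares(
                lambda th: model(th) - noisy.ravel(),
                x0=[rec.x, rec.y, rec.alpha, rec.tau, rec.d])
            # both estimators agree and stay near the generating pose
            assert math.hypot(rec.x - sol.x[0], rec.y - sol.x[1]) < 0.1
            pos_err.append(math.hypot(rec.x - pose.x, rec.y - pose.y))
            alpha_err.append(abs(wrap_angle(rec.alpha - pose.alpha)))
        assert np.mean(pos_err) < 0.15
        assert np.mean(alpha_err) < 0.5

    def test_reconstruction_error_monotone_in_projection_angle(self, geom, placement):
        """Fixed landmark noise hurts more as |tau| approaches 90 deg."""
        rng = np.random.default_rng(5)
        means = []
        for tau in (60.0, 70.0, 80.0, 85.0):
            errs = []
            for _ in range(400):
                pose = Pose(500, 500, float(rng.uniform(-180, 180)), tau, 900)
                pts = landmarks_from_pose(pose, geom, placement).points
                pts = pts + rng.normal(0, 0.05, size=pts.shape)
                try:
                    rec, _ = pose_from_landmarks(
                        ImageLandmarks(points=pts), placement, geom)
                    errs.append(abs(wrap_angle(rec.alpha - pose.alpha)))
                except GeometryError:
                    errs.append(90.0)
            means.append(np.mean(errs))
        assert all(b >= a for a, b in zip(means, means[1:]))
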