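"""Anatomical frames, Cardan decomposition and effective-leg variables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quailkin.geometry import (GimbalLockWarning, cardan_zxy, compose_zxy,
                               rot_x, rot_y, rot_z)
from quailkin.kinematics import (aperture_angle, compute_angle_table,
                                 differentiate, effective_leg, hip_angles,
                                 joint_angle, pelvis_frame,
                                 pelvis_global_angles, whole_leg_frame)

angles_st = st.floats(-170.0, 170.0)
mid_st = st.floats(-85.0, 85.0)


class TestCardan:
    def test_identity(self):
        assert cardan_zxy(np.eye(3)) == pytest.approx((0.0, 0.0, 0.0))

    def test_single_axis(self):
        g, a, b = cardan_zxy(rot_y(30.0))
        assert (g, a, b) == pytest.approx((0.0, 0.0, 30.0), abs=1e-12)

    def test_matrix_product_oracle(self):
        R = rot_z(10.0) @ rot_x(5.0) @ rot_y(20.0)
        g, a, b = cardan_zxy(R)
        assert (g, a, b) == pytest.approx((10.0, 5.0, 20.0), abs=1e-9)

    @settings(max_examples=150, deadline=None)
    @given(angles_st, mid_st, angles_st)
    def test_left_inverse_of_composition(self, gamma, alpha, beta):
        R = compose_zxy(gamma, alpha, beta)
        g, a, b = cardan_zxy(R)
        err = np.abs(compose_zxy(g, a, b) - R).max()
        assert err < 1e-9

    def test_gimbal_lock_warns(self):
        with pytest.warns(GimbalLockWarning):
            cardan_zxy(compose_zxy(10.0, 89.9, 5.0))

    def test_reflection_rejected(self):
        M = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            cardan_zxy(M)


class TestPelvisFrame:
    def test_hand_computed_example(self):
        f = pelvis_frame(np.array([0.02, 0, 0]), np.array([0, -0.01, 0]),
                         np.array([0, 0.01, 0]))
        np.testing.assert_allclose(f.basis[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(f.origin[0], [0.02 / 3, 0, 0], atol=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10**6))
    def test_orthonormal_right_handed(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3))
        if np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) < 1e-3:
            return
        f = pelvis_frame(pts[0], pts[1], pts[2])
        B = f.basis[0]
        np.testing.assert_allclose(B @ B.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(B) == pytest.approx(1.0)

    def test_equivariance_under_rotation(self):
        R = compose_zxy(23.0, 11.0, -40.0)
        pts = [np.array([0.02, 0.0, 0.0]), np.array([0.0, -0.01, 0.0]),
               np.array([0.0, 0.01, 0.0])]
        f0 = pelvis_frame(*pts)
        f1 = pelvis_frame(*[p @ R.T for p in pts])
        np.testing.assert_allclose(f1.basis[0], R @ f0.basis[0], atol=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            pelvis_frame(np.array([2.0, 0, 0]), np.array([0.0, 0, 0]),
                         np.array([1.0, 0, 0]))


class TestWholeLegFrame:
    def test_vertical_chain(self):
        f = whole_leg_frame(np.array([0, 0, 0.1]), np.array([0, 0, 0.05]),
                            np.array([0.001, 0, 0.0]), "l")
        np.testing.assert_allclose(f.basis[0][:, 2], [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(f.origin[0], [0, 0, 0.075])

    def test_plane_normal_points_left(self, level_trial):
        """e_y is the hip/knee/TMP-plane normal toward the animal's left."""
        lm = level_trial.landmarks
        for s in ("l", "r"):
            f = whole_leg_frame(lm[f"h_{s}"], lm[f"k_{s}"],
                                lm[f"tmp_dist_{s}"], s)
            assert np.all(f.basis[:, 1, 1] > 0)   # global +y = left

    def test_extended_leg_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            whole_leg_frame(np.array([0, 0, 0.2]), np.array([0, 0, 0.1]),
                            np.array([0, 0, 0.0]), "l")
        with pytest.raises(ValueError, match="side"):
            whole_leg_frame(np.zeros(3), np.zeros(3), np.zeros(3), "left")


class TestHipAndPelvisAngles:
    def test_aligned_frames_give_neutral_angles(self):
        from quailkin.kinematics import BodyFrame
        eye = BodyFrame(np.zeros((1, 3)), np.eye(3)[None], "pelvis")
        leg = BodyFrame(np.zeros((1, 3)), np.eye(3)[None], "whole-leg-l")
        res = hip_angles(eye, leg, "l")
        assert res.alpha[0] == pytest.approx(0.0)
        assert res.gamma[0] == pytest.approx(0.0)
        assert res.flexion_extension[0] == pytest.approx(90.0)

    def test_level_trial_recovers_template_hip_angles(self, level_trial):
        lm = level_trial.landmarks
        pel = pelvis_frame(lm["p_c"], lm["h_r"], lm["h_l"])
        for s in ("l", "r"):
            leg = whole_leg_frame(lm[f"h_{s}"], lm[f"k_{s}"],
                                  lm[f"tmp_dist_{s}"], s)
            hip = hip_angles(pel, leg, s)
            np.testing.assert_allclose(
                hip.flexion_extension,
                level_trial.angle_series("hip_flexion", s), atol=1e-8)
            np.testing.assert_allclose(
                hip.gamma, level_trial.angle_series("hip_abduction", s),
                atol=1e-8)

    def test_pelvis_pitch_sign_convention(self):
        """A nose-down rotation is positive pitch; retroversion negative."""
        from quailkin.kinematics import BodyFrame
        f = BodyFrame(np.zeros((1, 3)), compose_zxy(0.0, 0.0, -10.0)[None],
                      "pelvis")
        res = pelvis_global_angles(f)
        assert res.beta[0] == pytest.approx(-10.0)

    def test_pelvis_yaw_toward_left(self):
        from quailkin.kinematics import BodyFrame
        f = BodyFrame(np.zeros((1, 3)), compose_zxy(8.0, 0.0, 0.0)[None],
                      "pelvis")
        assert pelvis_global_angles(f).gamma[0] == pytest.approx(8.0)

    def test_angles_invariant_under_global_rigid_motion(self, level_trial):
        lm = level_trial.landmarks
        R = compose_zxy(31.0, 12.0, -25.0)
        shift = np.array([1.0, -2.0, 0.5])
        moved = {k: v @ R.T + shift for k, v in lm.items()}
        pel0 = pelvis_frame(lm["p_c"], lm["h_r"], lm["h_l"])
        pel1 = pelvis_frame(moved["p_c"], moved["h_r"], moved["h_l"])
        leg0 = whole_leg_frame(lm["h_l"], lm["k_l"], lm["tmp_dist_l"], "l")
        leg1 = whole_leg_frame(moved["h_l"], moved["k_l"],
                               moved["tmp_dist_l"], "l")
        a0 = hip_angles(pel0, leg0, "l")
        a1 = hip_angles(pel1, leg1, "l")
        np.testing.assert_allclose(a1.beta, a0.beta, atol=1e-8)
        np.testing.assert_allclose(a1.alpha, a0.alpha, atol=1e-8)
        np.testing.assert_allclose(a1.gamma, a0.gamma, atol=1e-8)

    def test_mirror_image_trial_gives_identical_curves(self, level_trial):
        """Analyzing the y-mirrored motion with swapped sides reproduces
        the original left-leg series (the right-leg sign convention)."""
        lm = level_trial.landmarks

        def mirror(name):
            flip = {"l": "r", "r": "l", "left": "right", "right": "left"}
            parts = name.rsplit("_", 1)
            if len(parts) == 2 and parts[1] in flip:
                return f"{parts[0]}_{flip[parts[1]]}"
            return name

        mirrored = {mirror(k): v * np.array([1.0, -1.0, 1.0])
                    for k, v in lm.items()}
        pel0 = pelvis_frame(lm["p_c"], lm["h_r"], lm["h_l"])
        pel1 = pelvis_frame(mirrored["p_c"], mirrored["h_r"], mirrored["h_l"])
        leg0 = whole_leg_frame(lm["h_l"], lm["k_l"], lm["tmp_dist_l"], "l")
        leg1 = whole_leg_frame(mirrored["h_r"], mirrored["k_r"],
                               mirrored["tmp_dist_r"], "r")
        a0 = hip_angles(pel0, leg0, "l")
        a1 = hip_angles(pel1, leg1, "r")
        np.testing.assert_allclose(a1.flexion_extension, a0.flexion_extension,
                                   atol=1e-8)
        np.testing.assert_allclose(a1.alpha, a0.alpha, atol=1e-8)
        np.testing.assert_allclose(a1.gamma, a0.gamma, atol=1e-8)


class TestJointAngle:
    def test_collinear_and_right_angle(self):
        p, j = np.array([0, 0, 2.0]), np.array([0, 0, 1.0])
        assert joint_angle(p, j, np.array([0, 0, 0.0]))[0] == pytest.approx(180.0)
        assert joint_angle(p, j, np.array([1, 0, 1.0]))[0] == pytest.approx(90.0)

    def test_level_trial_knee_at_td(self, level_trial):
        lm = level_trial.landmarks
        knee = joint_angle(lm["h_l"], lm["k_l"], lm["int_prox_l"])
        assert knee[0] == pytest.approx(120.0, abs=1e-6)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            joint_angle(np.zeros(3), np.zeros(3), np.ones(3))


class TestEffectiveLeg:
    def test_vertical_leg(self):
        l, a = effective_leg(np.array([0, 0, 0.1]), np.array([0, 0, 0.0]))
        assert l[0] == pytest.approx(0.1)
        assert a[0] == pytest.approx(90.0)

    def test_cranial_and_caudal_toe(self):
        hip = np.array([0, 0, 0.10])
        l, a = effective_leg(hip, np.array([0.05, 0, 0.0]))
        assert l[0] == pytest.approx(0.1118, abs=1e-4)
        assert a[0] == pytest.approx(63.43, abs=0.01)
        _, a2 = effective_leg(hip, np.array([-0.05, 0, 0.0]))
        assert a2[0] == pytest.approx(116.57, abs=0.01)

    def test_aperture_parallel_orthogonal_symmetric(self):
        hip_l, hip_r = np.array([0, 0.01, 0.1]), np.array([0, -0.01, 0.1])
        down = np.array([0, 0, -0.1])
        fwd = np.array([0.1, 0, 0.0])
        assert aperture_angle(hip_l, hip_l + down, hip_r, hip_r + down)[0] \
            == pytest.approx(0.0, abs=1e-9)
        assert aperture_angle(hip_l, hip_l + down, hip_r, hip_r + fwd)[0] \
            == pytest.approx(90.0)
        a = aperture_angle(hip_l, hip_l + down, hip_r, hip_r + fwd)
        b = aperture_angle(hip_r, hip_r + fwd, hip_l, hip_l + down)
        assert a[0] == pytest.approx(b[0])


class TestDifferentiate:
    def test_constant_and_ramp(self):
        assert np.allclose(differentiate(np.full(50, 3.0), 500.0), 0.0)
        ramp = np.arange(100) * 0.02
        v = differentiate(ramp, 500.0, lowpass_hz=None)
        np.testing.assert_allclose(v[1:-1], 0.02 * 500.0)

    def test_sine_derivative_amplitude(self):
        fps, f = 500.0, 5.0
        t = np.arange(1000) / fps
        v = differentiate(np.sin(2 * np.pi * f * t), fps)
        want = 2 * np.pi * f
        mid = v[100:-100]
        assert np.abs(mid).max() == pytest.approx(want, rel=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            differentiate(np.array([1.0, 2.0]), 100.0)


def test_full_noiseless_pipeline_recovers_ground_truth(noiseless_chain):
    """simulate -> project (noiseless) -> triangulate -> kinematics
    reproduces the generator's angle table within 0.1 degree."""
    tr = noiseless_chain["sim"]["trial"]
    positions = noiseless_chain["reconstruct"]["trajectory"].as_dict()
    # triangulated from *noiseless true* observations (bypass the tracker)
    cams = noiseless_chain["reconstruct"]["cameras"]
    from quailkin.reconstruct import triangulate
    obs = noiseless_chain["sim"]["observations"]
    traj = triangulate(cams["ventrodorsal"], cams["lateral"],
                       obs["ventrodorsal"], obs["lateral"])
    table = compute_angle_table(traj.as_dict(), 500.0)
    for var in ("hip_flexion", "hip_mediolateral", "hip_abduction",
                "knee", "int", "tmp"):
        for s in ("l", "r"):
            got = table[(table.variable == var)
                        & (table.side == s)].sort_values("frame").value_deg
            want = tr.angle_series(var, s)
            assert np.abs(got.to_numpy() - want).max() < 0.1, (var, s)
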