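"""Rotation and ZYX Euler-angle kinematics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from jointkin.rotations import (
    GRAVITY,
    EulerZYX,
    SingularAttitudeError,
    UnidentifiableRotationError,
    UnobservableAttitudeError,
    accel_roll_pitch,
    best_fit_rotation,
    body_gravity,
    body_rates_to_euler_rates,
    elemental_rotation,
    euler_rates_to_body_rates,
    hinge_angle_from_relative,
    is_rotation,
    rotation_about_axis,
    rotation_to_euler_zyx,
)

angles = st.floats(-3.0, 3.0)
safe_pitch = st.floats(-1.4, 1.4)


def oracle_body_gravity(a, b, c, g=GRAVITY):
    """Independent explicit three-matrix product: GX * GY * GZ * [0,0,g]."""
    def rx(t):
        return np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])

    return rx(-c) @ ry(-b) @ rz(-a) @ np.array([0.0, 0.0, g])


class TestElementalRotation:
    def test_zero_angle_is_identity(self):
        assert np.allclose(elemental_rotation("z", 0.0), np.eye(3))

    def test_quarter_turn_about_z(self):
        assert np.allclose(
            elemental_rotation("z", np.pi / 2) @ [1, 0, 0], [0, 1, 0], atol=1e-12
        )

    @pytest.mark.parametrize("t1,t2", [(0.3, 0.5), (-1.2, 2.0), (0.0, -0.7)])
    def test_same_axis_additivity(self, t1, t2):
        lhs = elemental_rotation("x", t1) @ elemental_rotation("x", t2)
        assert np.allclose(lhs, elemental_rotation("x", t1 + t2), atol=1e-12)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            elemental_rotation("x", np.nan)

    @given(axis=st.sampled_from("xyz"), angle=angles)
    def test_always_a_proper_rotation(self, axis, angle):
        assert is_rotation(elemental_rotation(axis, angle))


class TestBodyGravity:
    def test_zero_attitude(self):
        assert np.allclose(body_gravity(EulerZYX(0, 0, 0)), [0, 0, GRAVITY])

    @pytest.mark.parametrize("yaw", [0.0, 0.8, -2.5])
    def test_yaw_invariance(self, yaw):
        # rotation about the vertical leaves gravity unchanged
        assert np.allclose(body_gravity(EulerZYX(yaw, 0, 0)), [0, 0, GRAVITY])

    def test_matches_explicit_matrix_oracle(self):
        got = body_gravity(EulerZYX(0.3, 0.4, 0.5))
        assert np.allclose(got, oracle_body_gravity(0.3, 0.4, 0.5), atol=1e-12)

    @given(a=angles, b=safe_pitch, c=angles)
    def test_norm_conservation(self, a, b, c):
        assert np.linalg.norm(body_gravity(EulerZYX(a, b, c))) == pytest.approx(GRAVITY)

    def test_singular_pitch_rejected_by_type(self):
        with pytest.raises(SingularAttitudeError):
            EulerZYX(0.0, np.pi / 2, 0.0)


class TestAccelRollPitch:
    def test_level(self):
        assert accel_roll_pitch(np.array([0, 0, GRAVITY])) == (0.0, 0.0)

    def test_zero_vector_unobservable(self):
        with pytest.raises(UnobservableAttitudeError):
            accel_roll_pitch(np.zeros(3))

    @pytest.mark.parametrize("a", [0.0, 1.1, -2.0])
    @pytest.mark.parametrize("b", [-1.2, -0.4, 0.0, 0.9])
    @pytest.mark.parametrize("c", [-2.5, 0.0, 0.7, 2.9])
    def test_roundtrip_over_attitude_grid(self, a, b, c):
        roll, pitch = accel_roll_pitch(body_gravity(EulerZYX(a, b, c)))
        assert roll == pytest.approx(c, abs=1e-12)
        assert pitch == pytest.approx(b, abs=1e-12)


class TestEulerRateKinematics:
    def test_zero_attitude_reorders_axes(self):
        got = euler_rates_to_body_rates(EulerZYX(0, 0, 0), [0.1, 0.2, 0.3])
        assert np.allclose(got, [0.3, 0.2, 0.1])

    def test_term_by_term_oracle(self):
        att = EulerZYX(0.7, -0.3, 1.1)
        da, db, dc = 0.4, -0.2, 0.9

        def rx(t):
            return np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])

        def ry(t):
            return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])

        expected = (
            rx(-1.1) @ ry(0.3) @ [0, 0, da] + rx(-1.1) @ [0, db, 0] + np.array([dc, 0, 0])
        )
        got = euler_rates_to_body_rates(att, [da, db, dc])
        assert np.allclose(got, expected, atol=1e-12)

    @given(a=angles, b=safe_pitch, c=angles, r1=angles, r2=angles, r3=angles)
    def test_mutual_inverse(self, a, b, c, r1, r2, r3):
        att = EulerZYX(a, b, c)
        omega = euler_rates_to_body_rates(att, [r1, r2, r3])
        back = body_rates_to_euler_rates(att, omega)
        assert np.allclose(back, [r1, r2, r3], atol=1e-10)

    def test_finite_difference_consistency(self):
        # smooth Euler trajectory at 1 kHz: reconstructed rates match central
        # differences of the angles
        t = np.arange(0, 1.0, 1e-3)
        a = 0.5 * np.sin(2 * np.pi * t)
        b = 0.3 * np.sin(2 * np.pi * 0.7 * t)
        c = 0.4 * np.cos(2 * np.pi * 0.5 * t)
        traj = np.column_stack([a, b, c])
        rates_fd = np.gradient(traj, 1e-3, axis=0)
        for k in range(100, 900, 100):
            att = EulerZYX(*traj[k])
            omega = euler_rates_to_body_rates(att, rates_fd[k])
            back = body_rates_to_euler_rates(att, omega)
            assert np.allclose(back, rates_fd[k], atol=1e-3)

    def test_gimbal_lock_rejected(self):
        att = EulerZYX(0.0, np.pi / 2 - 1e-5, 0.0)
        with pytest.raises(SingularAttitudeError):
            body_rates_to_euler_rates(att, [0.1, 0.1, 0.1])


class TestBestFitRotation:
    def test_identity_on_equal_pairs(self):
        v = np.array([[1.0, 0, 0], [0, 1, 0], [0.3, 0.4, 0.5]])
        assert np.allclose(best_fit_rotation(v, v), np.eye(3), atol=1e-12)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(11)
        R0 = Rotation.random(random_state=7).as_matrix()
        v1 = rng.normal(size=(5, 3))
        R = best_fit_rotation(v1, v1 @ R0.T)
        assert np.linalg.norm(R - R0) < 1e-9

    def test_determinant_forced_positive_on_noisy_pairs(self):
        # near-planar pairs with heavy noise can make plain U V' a reflection
        rng = np.random.default_rng(3)
        for _ in range(50):
            v1 = rng.normal(size=(3, 3))
            v2 = rng.normal(size=(3, 3))
            R = best_fit_rotation(v1, v2)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert is_rotation(R)

    def test_collinear_pairs_unidentifiable(self):
        v1 = np.array([[1.0, 0, 0], [2.0, 0, 0], [-1.0, 0, 0]])
        with pytest.raises(UnidentifiableRotationError):
            best_fit_rotation(v1, v1)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        v1 = rng.normal(size=(8, 3))
        v2 = rng.normal(size=(8, 3))
        R = best_fit_rotation(v1, v2)
        R_ref = Rotation.align_vectors(v2, v1)[0].as_matrix()
        assert np.allclose(R, R_ref, atol=1e-9)

    def test_matches_exhaustive_grid_on_toy_instance(self):
        # planar 2-pair toy problem: sweep rotations about z on a fine grid
        v1 = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        theta0 = 0.83
        Rz = elemental_rotation("z", theta0)
        v2 = v1 @ Rz.T
        grid = np.linspace(-np.pi, np.pi, 20001)
        costs = [np.sum((v1 @ elemental_rotation("z", g).T - v2) ** 2) for g in grid]
        g_best = grid[int(np.argmin(costs))]
        R = best_fit_rotation(v1, v2)
        assert hinge_angle_from_relative  # quiet linters; angle read below
        ang = np.arctan2(R[1, 0], R[0, 0])
        assert abs(ang - g_best) < (grid[1] - grid[0])


class TestHingeAngle:
    def test_identity_gives_zero(self):
        assert hinge_angle_from_relative(np.eye(3)) == 0.0

    @pytest.mark.parametrize("theta", [-3.0, -1.2, 0.0, 0.4, 2.9])
    def test_x_rotation_recovered(self, theta):
        R = elemental_rotation("x", theta)
        assert hinge_angle_from_relative(R) == pytest.approx(theta, abs=1e-12)

    def test_composed_hinge_trace(self):
        # composing known hinge rotations reproduces the truth angle trace
        thetas = np.linspace(-2.5, 2.5, 101)
        R_acc = np.eye(3)
        prev = 0.0
        for th in thetas:
            R_acc = R_acc @ elemental_rotation("x", th - prev)
            prev = th
            assert hinge_angle_from_relative(R_acc) == pytest.approx(th, abs=1e-12)


class TestEulerDecomposition:
    @given(a=angles, b=safe_pitch, c=angles)
    def test_matrix_roundtrip(self, a, b, c):
        att = EulerZYX(a, b, c)
        back = rotation_to_euler_zyx(att.rotation_matrix())
        assert np.allclose(
            [np.sin(back.yaw - a), back.pitch - b, np.sin(back.roll - c)],
            0.0,
            atol=1e-9,
        )

    def test_rodrigues_matches_elemental(self):
        assert np.allclose(
            rotation_about_axis([0, 0, 1], 0.7), elemental_rotation("z", 0.7), atol=1e-12
        )
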