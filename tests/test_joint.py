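"""Hinge-joint self-calibration and joint-angle estimation."""

import time

import numpy as np
import pytest

import jointkin as jk
from conftest import aligned_rmse_deg, axis_error_deg
from jointkin.joint import (
    InsufficientExcitationError,
    JointCalibration,
    axis_residual,
    build_joint_dataset,
    center_residual,
    central_difference,
    estimate_joint_axes,
    estimate_joint_centers,
    fuse_joint_angles,
    joint_angle_accel,
    joint_angle_gyro,
    joint_angle_pipeline,
    joint_angle_svd,
    lever_gauge,
    range_of_motion,
    rotational_accel,
)
from jointkin.denoise import lowpass_imu
from jointkin.protocols import calibration_motion, measurement_motion, standard_rig
from jointkin.sim import (
    BaseWobble,
    ImuSeries,
    MotionProfile,
    SensorErrorModel,
    SinusoidProfile,
    StepProfile,
    simulate_hinge,
    with_seed,
)

NOISY = SensorErrorModel(accel_noise_sd=0.05, gyro_noise_sd=0.02)


@pytest.fixture(scope="module")
def still_ds(rig):
    motion = MotionProfile(
        hinge=SinusoidProfile(amp_deg=0.0, freq_hz=0.5),
        duration=5.0, still_before=2.0, still_after=2.0,
    )
    return simulate_hinge(rig, motion)


@pytest.fixture(scope="module")
def noisy_cal(cal_ds):
    i1 = jk.corrupt(cal_ds.imu1, with_seed(NOISY, 101))
    i2 = jk.corrupt(cal_ds.imu2, with_seed(NOISY, 202))
    return build_joint_dataset(lowpass_imu(i1, 4.0), lowpass_imu(i2, 4.0))


class TestBuildJointDataset:
    def test_constant_rate_has_zero_derivative(self):
        n = 100
        t = np.arange(n) / 100.0
        g = np.tile([0.1, -0.2, 0.3], (n, 1))
        a = np.tile([0, 0, 9.81], (n, 1))
        s = ImuSeries(t=t, accel=a, gyro=g)
        W = build_joint_dataset(s, s)
        assert np.max(np.abs(W.dg1)) < 1e-12

    def test_linear_ramp_derivative_exact(self):
        n = 100
        t = np.arange(n) / 100.0
        g = np.outer(t, [1.0, -2.0, 0.5])
        s = ImuSeries(t=t, accel=np.tile([0, 0, 9.81], (n, 1)), gyro=g)
        W = build_joint_dataset(s, s)
        assert np.allclose(W.dg1, np.tile([1.0, -2.0, 0.5], (n, 1)), atol=1e-9)

    def test_quadratic_interior_exact_endpoint_first_order(self):
        dt = 0.01
        t = np.arange(200) * dt
        y = t[:, None] ** 2
        d = central_difference(y, dt)
        assert np.max(np.abs(d[2:-2, 0] - 2 * t[2:-2])) < 1e-9
        assert abs(d[0, 0] - 0.0) <= 2 * dt  # one-sided Taylor error O(dt)

    def test_timestamp_mismatch_rejected(self, cal_ds, meas_ds):
        with pytest.raises(ValueError):
            build_joint_dataset(cal_ds.imu1, meas_ds.imu1)


class TestAxisConstraint:
    def test_zero_residual_at_truth(self, cal_ds):
        c = cal_ds.calibration
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        r = axis_residual(W.g1, W.g2, c.j1, c.j2)
        assert np.max(np.abs(r)) < 1e-9

    def test_sign_symmetry(self, cal_ds):
        c = cal_ds.calibration
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        r1 = axis_residual(W.g1, W.g2, c.j1, c.j2)
        r2 = axis_residual(W.g1, W.g2, -c.j1, -c.j2)
        assert np.allclose(r1, r2, atol=1e-12)

    def test_wrong_axes_nonzero(self, cal_ds):
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        r = axis_residual(W.g1, W.g2, [0, 1, 0], [0, 0, 1])
        assert np.max(np.abs(r)) > 0.01

    def test_non_unit_axis_rejected(self, cal_ds):
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        with pytest.raises(ValueError):
            axis_residual(W.g1, W.g2, [0, 2, 0], [0, 0, 1])

    def test_truth_beats_random_axis_pairs(self, cal_ds):
        # global-minimum sanity: the truth cost is below 1000 random pairs
        c = cal_ds.calibration
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        cost_truth = float(np.sum(axis_residual(W.g1, W.g2, c.j1, c.j2) ** 2))
        rng = np.random.default_rng(17)
        dirs = rng.normal(size=(1000, 2, 3))
        dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
        n1 = np.linalg.norm(np.cross(W.g1[None, :, :], dirs[:, None, 0, :]), axis=2)
        n2 = np.linalg.norm(np.cross(W.g2[None, :, :], dirs[:, None, 1, :]), axis=2)
        costs = np.sum((n1 - n2) ** 2, axis=1)
        assert cost_truth <= float(np.min(costs))


class TestEstimateJointAxes:
    def test_noise_free_recovery(self, cal_ds):
        c = cal_ds.calibration
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        j1, j2, rms = estimate_joint_axes(W)
        assert axis_error_deg(j1, c.j1) < 0.5
        assert axis_error_deg(j2, c.j2) < 0.5
        assert rms < 1e-6

    def test_noisy_recovery(self, cal_ds, noisy_cal):
        c = cal_ds.calibration
        j1, j2, _ = estimate_joint_axes(noisy_cal)
        assert axis_error_deg(j1, c.j1) < 2.0
        assert axis_error_deg(j2, c.j2) < 2.0

    def test_consistent_pair_orientation(self, noisy_cal, cal_ds):
        # both axes land on the same side: their truth-projections agree in sign
        c = cal_ds.calibration
        j1, j2, _ = estimate_joint_axes(noisy_cal)
        assert np.sign(j1 @ c.j1) == np.sign(j2 @ c.j2)

    def test_still_record_unidentifiable(self, still_ds):
        W = build_joint_dataset(still_ds.imu1, still_ds.imu2)
        with pytest.raises(InsufficientExcitationError):
            estimate_joint_axes(W)


class TestRotationalAccel:
    def test_zero_lever(self):
        assert np.allclose(rotational_accel([1.0, 2, 3], [0.1, 0, 0], [0, 0, 0]), 0.0)

    def test_pure_centripetal(self):
        # spin about z at rate w, lever r along x: Gamma = -w^2 r x_hat
        w, r = 3.0, 0.25
        out = rotational_accel([0, 0, w], [0, 0, 0], [r, 0, 0])
        assert np.allclose(out, [-w * w * r, 0, 0], atol=1e-12)

    def test_pure_tangential(self):
        out = rotational_accel([0, 0, 0], [0, 0, 2.0], [0.1, 0, 0])
        assert np.allclose(out, [0, 0.2, 0], atol=1e-12)


class TestCenterConstraint:
    def test_zero_residual_at_truth_with_analytic_derivatives(self, cal_ds):
        c = cal_ds.calibration
        r = center_residual(
            cal_ds.imu1.accel, cal_ds.imu1.gyro, cal_ds.dgyro1,
            cal_ds.imu2.accel, cal_ds.imu2.gyro, cal_ds.dgyro2,
            c.o1, c.o2,
        )
        assert np.max(np.abs(r)) < 1e-8

    def test_colocated_sensors_zero_levers(self, rig):
        rig0 = jk.HingeRigConfig(lever1=(0, 0, 0), lever2=(0, 0, 0))
        ds = simulate_hinge(rig0, calibration_motion())
        r = center_residual(
            ds.imu1.accel, ds.imu1.gyro, ds.dgyro1,
            ds.imu2.accel, ds.imu2.gyro, ds.dgyro2,
            np.zeros(3), np.zeros(3),
        )
        assert np.max(np.abs(r)) < 1e-8

    def test_residual_grows_along_perturbation_ray(self, cal_ds):
        c = cal_ds.calibration
        d = np.array([0.0, 1.0, 0.0])
        norms = []
        for s in (0.0, 0.02, 0.05, 0.1):
            r = center_residual(
                cal_ds.imu1.accel, cal_ds.imu1.gyro, cal_ds.dgyro1,
                cal_ds.imu2.accel, cal_ds.imu2.gyro, cal_ds.dgyro2,
                c.o1 + s * d, c.o2,
            )
            norms.append(float(np.sqrt(np.mean(np.asarray(r) ** 2))))
        assert norms == sorted(norms)


class TestEstimateJointCenters:
    def test_noise_free_recovery(self, cal_ds):
        c = cal_ds.calibration
        W = build_joint_dataset(cal_ds.imu1, cal_ds.imu2)
        j1, j2, _ = estimate_joint_axes(W)
        o1, o2, _ = estimate_joint_centers(W, j1, j2)
        t1, t2 = lever_gauge(c.o1, c.o2, c.j1, c.j2)
        assert np.linalg.norm(o1 - t1) < 0.005
        assert np.linalg.norm(o2 - t2) < 0.005

    def test_noisy_recovery(self, cal_ds, noisy_cal):
        c = cal_ds.calibration
        calib = jk.calibrate(noisy_cal)
        t1, t2 = lever_gauge(c.o1, c.o2, c.j1, c.j2)
        e1, e2 = lever_gauge(calib.o1, calib.o2, calib.j1, calib.j2)
        assert np.linalg.norm(e1 - t1) < 0.015
        assert np.linalg.norm(e2 - t2) < 0.015

    def test_constant_rate_unidentifiable(self, rig):
        motion = MotionProfile(hinge=jk.RampProfile(rate_deg_s=30.0), duration=5.0)
        ds = simulate_hinge(rig, motion)
        W = build_joint_dataset(ds.imu1, ds.imu2)
        with pytest.raises(InsufficientExcitationError):
            estimate_joint_centers(W)

    def test_still_record_unidentifiable(self, still_ds):
        W = build_joint_dataset(still_ds.imu1, still_ds.imu2)
        with pytest.raises(InsufficientExcitationError):
            estimate_joint_centers(W)


class TestJointAngleGyro:
    def test_constant_rate_integrates_exactly(self, rig):
        motion = MotionProfile(hinge=jk.RampProfile(rate_deg_s=20.0), duration=4.0)
        ds = simulate_hinge(rig, motion)
        c = ds.calibration
        W = build_joint_dataset(ds.imu1, ds.imu2)
        tr = joint_angle_gyro(W, c.j1, c.j2, alpha0=0.0)
        assert np.degrees(tr.angle[-1]) == pytest.approx(80.0, abs=1e-6)

    def test_still_record_holds_alpha0(self, still_ds):
        W = build_joint_dataset(still_ds.imu1, still_ds.imu2)
        tr = joint_angle_gyro(W, still_ds.calibration.j1, still_ds.calibration.j2,
                              alpha0=0.3)
        assert np.allclose(tr.angle, 0.3)

    def test_common_mode_bias_cancels_single_sensor_bias_drifts(self, still_ds):
        c = still_ds.calibration
        beta = 0.02
        b1 = jk.corrupt(still_ds.imu1, SensorErrorModel(gyro_bias=tuple(beta * c.j1)))
        b2 = jk.corrupt(still_ds.imu2, SensorErrorModel(gyro_bias=tuple(beta * c.j2)))
        W_common = build_joint_dataset(b1, b2)
        tr = joint_angle_gyro(W_common, c.j1, c.j2)
        assert np.max(np.abs(tr.angle)) < 1e-9  # equal axial biases cancel
        W_single = build_joint_dataset(b1, still_ds.imu2)
        tr1 = joint_angle_gyro(W_single, c.j1, c.j2)
        T = still_ds.t[-1]
        assert tr1.angle[-1] == pytest.approx(beta * T, rel=1e-6)


class TestJointAngleAccel:
    def test_slow_flexion_tracks_truth(self, meas_ds):
        c = meas_ds.calibration
        calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
        W = build_joint_dataset(meas_ds.imu1, meas_ds.imu2)
        tr = joint_angle_accel(W, calib, alpha0=0.0, still_interval=(0, 100))
        assert np.degrees(np.max(np.abs(tr.angle - meas_ds.truth_angle))) < 2.0 + 1.5

    def test_still_at_known_angle(self, rig):
        motion = MotionProfile(
            hinge=StepProfile(levels_deg=(0.0, 30.0), hold_s=4.0, transition_s=1.0),
            duration=9.0,
        )
        ds = simulate_hinge(rig, motion)
        c = ds.calibration
        calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
        W = build_joint_dataset(ds.imu1, ds.imu2)
        tr = joint_angle_accel(W, calib, alpha0=0.0, still_interval=(0, 200))
        final = np.degrees(np.mean(tr.angle[-200:]))
        assert final == pytest.approx(30.0, abs=0.5)


class TestFuseJointAngles:
    @staticmethod
    def _traces(meas_ds, seed):
        c = meas_ds.calibration
        calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
        err = SensorErrorModel(accel_noise_sd=0.05, gyro_noise_sd=0.005,
                               gyro_bias=(0.01, 0.002, -0.003))
        i1 = jk.corrupt(meas_ds.imu1, with_seed(err, seed))
        i2 = jk.corrupt(meas_ds.imu2, with_seed(err, seed + 1))
        W = build_joint_dataset(i1, i2)
        g = joint_angle_gyro(W, c.j1, c.j2)
        a = joint_angle_accel(W, calib, still_interval=(0, 150))
        return g, a

    def test_endpoint_coefficients(self, meas_ds):
        g, a = self._traces(meas_ds, 7)
        assert np.array_equal(fuse_joint_angles(a, g, 1.0).angle, g.angle)
        assert np.array_equal(fuse_joint_angles(a, g, 0.0).angle, a.angle)

    def test_fused_beats_both_sources(self, meas_ds):
        truth = meas_ds.truth_angle
        g, a = self._traces(meas_ds, 21)
        fused = fuse_joint_angles(a, g, 0.98)
        rmse = {
            tr.source: np.degrees(np.sqrt(np.mean((tr.angle - truth) ** 2)))
            for tr in (g, a, fused)
        }
        assert rmse["fused"] < min(rmse["gyro"], rmse["accel"])

    def test_mismatched_traces_rejected(self, meas_ds):
        g, a = self._traces(meas_ds, 3)
        short = jk.AngleTrace(t=g.t[:-1], angle=g.angle[:-1], source="gyro")
        with pytest.raises(ValueError):
            fuse_joint_angles(a, short)


class TestJointAngleSvd:
    @staticmethod
    @pytest.fixture(scope="class")
    def step_ds(rig):
        motion = MotionProfile(
            hinge=StepProfile(levels_deg=(0, 20, 40, 60), hold_s=3.0, transition_s=1.0),
            duration=16.0,
            base=(
                BaseWobble(axis=(0.5, 0.866, 0), profile=SinusoidProfile(amp_deg=6, freq_hz=0.5)),
                BaseWobble(axis=(0.45, 0, 0.893), profile=SinusoidProfile(amp_deg=5, freq_hz=0.75)),
            ),
        )
        return simulate_hinge(rig, motion)

    @staticmethod
    def _deep_hold_mask(ds, window_s=0.5):
        w = int(round(window_s * ds.imu1.rate))
        half = w // 2
        hold = np.abs(ds.truth_rate) < 1e-12
        deep = np.zeros_like(hold)
        for k in range(len(hold)):
            lo, hi = max(0, k - half), min(len(hold), k - half + w)
            deep[k] = hold[lo:hi].all()
        return deep

    def test_quasi_static_windows_exact(self, step_ds):
        c = step_ds.calibration
        calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
        tr = joint_angle_svd(step_ds.imu1, step_ds.imu2, window_s=0.5,
                             alpha0=step_ds.truth_angle[0], calibration=calib)
        deep = self._deep_hold_mask(step_ds)
        err = np.degrees(tr.angle - step_ds.truth_angle)
        assert np.max(np.abs(err[deep])) < 0.1

    def test_agreement_with_fused_route(self, step_ds):
        c = step_ds.calibration
        calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
        svd = joint_angle_svd(step_ds.imu1, step_ds.imu2, window_s=0.5,
                              alpha0=0.0, calibration=calib)
        res = joint_angle_pipeline(step_ds.imu1, step_ds.imu2, calibration=calib,
                                   denoise=False, alpha0=0.0,
                                   still_cfg=jk.StillnessConfig(threshold=1e-6))
        deep = self._deep_hold_mask(step_ds)
        diff = svd.angle[deep] - res["fused"].angle[deep]
        assert np.degrees(np.sqrt(np.mean(diff**2))) < 1.0

    def test_static_identical_vectors_unidentifiable(self, still_ds):
        with pytest.raises(InsufficientExcitationError):
            joint_angle_svd(still_ds.imu1, still_ds.imu2)


class TestRangeOfMotion:
    def test_sinusoid_range_twice_amplitude(self, rig):
        motion = MotionProfile(hinge=SinusoidProfile(amp_deg=30, freq_hz=0.5), duration=10.0)
        ds = simulate_hinge(rig, motion)
        rom = range_of_motion(jk.AngleTrace(t=ds.t, angle=ds.truth_angle))
        assert rom.range_deg == pytest.approx(60.0, abs=1e-9)

    def test_constant_trace(self):
        tr = jk.AngleTrace(t=np.arange(10.0), angle=np.full(10, 0.5))
        assert range_of_motion(tr).range_deg == 0.0

    def test_noisy_flexion_range(self, rig):
        motion = MotionProfile(hinge=SinusoidProfile(amp_deg=45, freq_hz=0.25),
                               duration=8.0)
        ds = simulate_hinge(rig, motion)
        rng = np.random.default_rng(9)
        noisy = ds.truth_angle + np.radians(rng.normal(0, 0.5, len(ds.t)))
        rom = range_of_motion(jk.AngleTrace(t=ds.t, angle=noisy))
        assert abs(rom.range_deg - 90.0) < 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            range_of_motion(jk.AngleTrace(t=np.array([]), angle=np.array([])))


class TestPipeline:
    def test_end_to_end_low_noise(self, cal_ds, meas_ds):
        low = jk.NOISE_PRESETS["low"]
        c1 = jk.corrupt(cal_ds.imu1, with_seed(low, 11))
        c2 = jk.corrupt(cal_ds.imu2, with_seed(low, 12))
        m1 = jk.corrupt(meas_ds.imu1, with_seed(low, 13))
        m2 = jk.corrupt(meas_ds.imu2, with_seed(low, 14))
        Wc = build_joint_dataset(lowpass_imu(c1, 4.0), lowpass_imu(c2, 4.0))
        calib = jk.calibrate(Wc)
        res = joint_angle_pipeline(m1, m2, calibration=calib, alpha0=0.0)
        assert aligned_rmse_deg(res["fused"].angle, meas_ds.truth_angle) <= 1.5
        rom = range_of_motion(res["fused"])
        truth_rom = np.ptp(np.degrees(meas_ds.truth_angle))
        assert abs(rom.range_deg - truth_rom) <= 2.0

    def test_runtime_scales_linearly(self, rig):
        def run(duration):
            ds = simulate_hinge(rig, measurement_motion(duration))
            c = ds.calibration
            calib = JointCalibration(j1=c.j1, j2=c.j2, o1=c.o1, o2=c.o2)
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                joint_angle_pipeline(ds.imu1, ds.imu2, calibration=calib)
                best = min(best, time.perf_counter() - t0)
            return best

        t_n = run(24.0)
        t_2n = run(48.0)
        assert t_2n <= 2.5 * t_n
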