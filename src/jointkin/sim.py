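"""Rigid-body simulator for two IMUs on a single-degree-of-freedom hinge limb.

Two segments share a hinge joint at the world origin.  Segment 1 (proximal)
optionally rotates about a fixed world axis ("base wobble", emulating whole-limb
motion); segment 2 (distal) additionally rotates about the hinge axis by the
joint angle theta(t).  Each segment carries one IMU at a fixed lever arm from
the joint center with a fixed mount orientation.  All kinematic quantities
(angular velocity, angular acceleration, point acceleration) are computed
analytically from the motion profile, so the generated streams are exact and
serve as the oracle for every downstream estimator.

Sensor models (additive noise, constant bias, bias random walk, soft-tissue
mount oscillation) are applied separately by :func:`corrupt`, leaving the clean
streams available as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .rotations import GRAVITY, rotation_about_axis

DEG = math.pi / 180.0


# --------------------------------------------------------------------------
# Time series containers
# --------------------------------------------------------------------------


@dataclass
class ImuSeries:
    """Uniformly sampled triaxial specific force + angular rate, sensor frame.

    accel in m/s^2, gyro in rad/s, timestamps in seconds.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("ImuSeries needs >= 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"shape mismatch: t {self.t.shape}, accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )
        dt = np.diff(self.t)
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite timestamps")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
            raise ValueError("timestamps are not uniform")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("non-finite samples")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class GpsSeries:
    """Position/velocity fix stream in the world frame (GPS-like)."""

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("empty GpsSeries")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("GPS timestamps must be strictly increasing")
        n = len(self.t)
        if self.pos.shape != (n, 3) or self.vel.shape != (n, 3):
            raise ValueError("GPS pos/vel shape mismatch")

    def __len__(self) -> int:
        return self.t.shape[0]


# --------------------------------------------------------------------------
# Motion profiles: analytic angle / rate / acceleration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SinusoidProfile:
    """Smooth oscillation theta(tau) = mean - amp*cos(2 pi f tau) (radians out).

    Starts and ends (after whole periods) at zero rate, so leading/trailing
    still segments join with continuous angular velocity.  Peak-to-peak range
    is 2*amp.
    """

    amp_deg: float
    freq_hz: float
    mean_deg: float | None = None  # default: amp, so motion starts at 0 deg

    def _mean(self) -> float:
        return self.amp_deg if self.mean_deg is None else self.mean_deg

    def angle(self, tau):
        w = 2 * math.pi * self.freq_hz
        return DEG * (self._mean() - self.amp_deg * np.cos(w * np.asarray(tau)))

    def rate(self, tau):
        w = 2 * math.pi * self.freq_hz
        return DEG * self.amp_deg * w * np.sin(w * np.asarray(tau))

    def accel(self, tau):
        w = 2 * math.pi * self.freq_hz
        return DEG * self.amp_deg * w * w * np.cos(w * np.asarray(tau))


@dataclass(frozen=True)
class RampProfile:
    """Linear angle ramp theta(tau) = start + rate*tau (radians out)."""

    rate_deg_s: float
    start_deg: float = 0.0

    def angle(self, tau):
        return DEG * (self.start_deg + self.rate_deg_s * np.asarray(tau))

    def rate(self, tau):
        return DEG * self.rate_deg_s * np.ones_like(np.asarray(tau, dtype=float))

    def accel(self, tau):
        return np.zeros_like(np.asarray(tau, dtype=float))


@dataclass(frozen=True)
class StepProfile:
    """Piecewise hold-and-move schedule through a list of angle levels.

    Holds each level for ``hold_s`` seconds, blending between consecutive
    levels over ``transition_s`` seconds with a cosine ramp (continuous angle
    and rate; bounded acceleration).  Past the last level the angle holds.
    """

    levels_deg: tuple[float, ...]
    hold_s: float = 3.0
    transition_s: float = 1.0

    def _pieces(self, tau):
        tau = np.asarray(tau, dtype=float)
        period = self.hold_s + self.transition_s
        k = np.minimum((tau // period).astype(int), len(self.levels_deg) - 1)
        frac = tau - k * period
        in_move = (frac > self.hold_s) & (k < len(self.levels_deg) - 1)
        s = np.where(in_move, (frac - self.hold_s) / self.transition_s, 0.0)
        return k, in_move, np.clip(s, 0.0, 1.0)

    def angle(self, tau):
        k, in_move, s = self._pieces(tau)
        lv = np.asarray(self.levels_deg, dtype=float)
        nxt = np.minimum(k + 1, len(lv) - 1)
        blend = 0.5 * (1.0 - np.cos(math.pi * s))
        return DEG * (lv[k] + (lv[nxt] - lv[k]) * blend)

    def rate(self, tau):
        k, in_move, s = self._pieces(tau)
        lv = np.asarray(self.levels_deg, dtype=float)
        nxt = np.minimum(k + 1, len(lv) - 1)
        r = 0.5 * math.pi / self.transition_s * np.sin(math.pi * s)
        return DEG * (lv[nxt] - lv[k]) * r * in_move

    def accel(self, tau):
        k, in_move, s = self._pieces(tau)
        lv = np.asarray(self.levels_deg, dtype=float)
        nxt = np.minimum(k + 1, len(lv) - 1)
        a = 0.5 * (math.pi / self.transition_s) ** 2 * np.cos(math.pi * s)
        return DEG * (lv[nxt] - lv[k]) * a * in_move


@dataclass(frozen=True)
class BaseWobble:
    """Whole-limb rotation about a fixed axis, driven by a profile."""

    axis: tuple[float, float, float]
    profile: SinusoidProfile | RampProfile


@dataclass(frozen=True)
class MotionProfile:
    """Joint-angle trajectory plus optional base rotation and still padding.

    ``hinge`` drives the joint angle; motion runs during
    [still_before, duration - still_after] and the angle is clamped (rates
    zero) outside that window.  ``base`` may be a single wobble or a tuple of
    wobbles composed in order; note that at least two independent rotation
    components are needed for the proximal segment's angular velocity to vary
    in direction (a single fixed-axis wobble leaves the constraint-based
    calibration of that sensor degenerate).
    """

    hinge: SinusoidProfile | RampProfile | StepProfile
    duration: float
    still_before: float = 0.0
    still_after: float = 0.0
    base: BaseWobble | tuple[BaseWobble, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.still_before + self.still_after >= self.duration:
            raise ValueError("still segments leave no room for motion")

    def _eval(self, profile, t: np.ndarray):
        t = np.asarray(t, dtype=float)
        t0, t1 = self.still_before, self.duration - self.still_after
        tau = np.clip(t, t0, t1) - t0
        moving = (t >= t0) & (t <= t1)
        ang = np.asarray(profile.angle(tau), dtype=float)
        rate = np.where(moving, profile.rate(tau), 0.0)
        acc = np.where(moving, profile.accel(tau), 0.0)
        return ang, rate, acc

    def hinge_angle(self, t):
        return self._eval(self.hinge, t)

    @property
    def wobbles(self) -> tuple[BaseWobble, ...]:
        if self.base is None:
            return ()
        if isinstance(self.base, BaseWobble):
            return (self.base,)
        return tuple(self.base)

    def base_angles(self, t):
        """Per-wobble (angle, rate, accel) arrays."""
        return [self._eval(w.profile, t) for w in self.wobbles]


# --------------------------------------------------------------------------
# Rig and error models
# --------------------------------------------------------------------------


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class HingeRigConfig:
    """Geometry of the two-segment hinge rig.

    axis : hinge axis, segment-1 frame (== world frame at the reference pose).
    mount1/mount2 : segment-to-sensor rotation matrices.
    lever1/lever2 : joint-center-to-sensor vectors, segment frames, meters.
    """

    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    mount1: np.ndarray = field(default_factory=lambda: np.eye(3))
    mount2: np.ndarray = field(default_factory=lambda: np.eye(3))
    lever1: tuple[float, float, float] = (0.03, 0.02, 0.24)
    lever2: tuple[float, float, float] = (0.02, -0.03, -0.20)
    gravity: float = GRAVITY
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sample rate must be > 0")
        if not np.all(np.isfinite(self.lever1)) or not np.all(np.isfinite(self.lever2)):
            raise ValueError("non-finite lever arms")
        _unit(self.axis)

    def truth_calibration(self) -> "JointCalibrationTruth":
        """Sensor-frame axes and lever arms implied by the mounts.

        The axes are oriented so that the axial angular-rate difference
        g1 . j1 - g2 . j2 equals +dtheta/dt (the flexion-rate convention the
        joint-angle estimators integrate): with the distal segment rotating by
        +theta about ``axis`` relative to the proximal one, that orientation
        is the negative of the mount-transformed axis.
        """
        ax = _unit(self.axis)
        m1 = np.asarray(self.mount1, dtype=float)
        m2 = np.asarray(self.mount2, dtype=float)
        return JointCalibrationTruth(
            j1=-(m1 @ ax),
            j2=-(m2 @ ax),
            o1=m1 @ np.asarray(self.lever1, float),
            o2=m2 @ np.asarray(self.lever2, float),
        )


@dataclass(frozen=True)
class JointCalibrationTruth:
    """True sensor-frame joint axes and lever arms of a simulated rig."""

    j1: np.ndarray
    j2: np.ndarray
    o1: np.ndarray
    o2: np.ndarray


@dataclass(frozen=True)
class SensorErrorModel:
    """Additive sensor error model for :func:`corrupt`.

    Soft-tissue artifact: a damped oscillation of the mount orientation about
    ``st_axis`` with initial amplitude ``st_amp_deg``, frequency ``st_freq_hz``
    and damping ``st_damping`` (1/s), optionally re-excited every
    ``st_retrigger_s`` seconds (skin/muscle wobble re-excited by movement).
    """

    accel_noise_sd: float = 0.0
    gyro_noise_sd: float = 0.0
    accel_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_bias_walk_sd: float = 0.0
    st_amp_deg: float = 0.0
    st_freq_hz: float = 8.0
    st_damping: float = 3.0
    st_axis: tuple[float, float, float] = (0.57735, 0.57735, 0.57735)
    st_retrigger_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.accel_noise_sd, self.gyro_noise_sd, self.gyro_bias_walk_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")


NOISE_PRESETS: dict[str, SensorErrorModel] = {
    "none": SensorErrorModel(),
    "low": SensorErrorModel(accel_noise_sd=0.02, gyro_noise_sd=0.003,
                            gyro_bias=(0.001, -0.0005, 0.0008)),
    "drift": SensorErrorModel(accel_noise_sd=0.02, gyro_noise_sd=0.003,
                              gyro_bias=(0.035, 0.01, -0.008)),
    "soft-tissue": SensorErrorModel(accel_noise_sd=0.02, gyro_noise_sd=0.003,
                                    st_amp_deg=5.0, st_retrigger_s=2.0),
}


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Simulator output: truth plus (clean) sensor streams on one clock."""

    t: np.ndarray
    imu1: ImuSeries
    imu2: ImuSeries
    dgyro1: np.ndarray               # analytic sensor-frame angular accel, rad/s^2
    dgyro2: np.ndarray
    truth_angle: np.ndarray          # joint angle, radians
    truth_rate: np.ndarray           # joint angular rate, rad/s
    truth_att1: np.ndarray           # sensor-1 ZYX Euler (n, 3): yaw, pitch, roll
    truth_att2: np.ndarray
    pos1: np.ndarray                 # sensor world positions, m
    vel1: np.ndarray
    pos2: np.ndarray
    vel2: np.ndarray
    calibration: JointCalibrationTruth
    rig: HingeRigConfig
    motion: MotionProfile


def simulate_hinge(rig: HingeRigConfig, motion: MotionProfile) -> SyntheticDataset:
    """Generate noise-free, kinematically exact streams for the hinge rig.

    Each sensor's gyro is the body-frame angular velocity of its segment; each
    accelerometer is the specific force at the sensor position (gravity plus
    the analytic lever-arm centripetal/tangential terms).
    """
    n = int(round(motion.duration * rig.rate)) + 1
    t = np.arange(n) / rig.rate

    theta, dtheta, ddtheta = motion.hinge_angle(t)

    axis = _unit(rig.axis)

    # compose base wobbles: R_base = R_1 R_2 ..., with world angular velocity
    # w = sum_i P_i (dphi_i a_i) where P_i is the product of wobbles before i;
    # the time derivative of each term adds w_{<i} x term_i.
    R_base = Rotation.identity(n)
    w1 = np.zeros((n, 3))
    dw1 = np.zeros((n, 3))
    for wob, (phi, dphi, ddphi) in zip(motion.wobbles, motion.base_angles(t)):
        a = _unit(wob.axis)
        a_w = R_base.apply(a)
        term = dphi[:, None] * a_w
        dw1 += ddphi[:, None] * a_w + np.cross(w1, term)
        w1 += term
        R_base = R_base * Rotation.from_rotvec(np.outer(phi, a))

    R_hinge = Rotation.from_rotvec(np.outer(theta, axis))
    R_seg1 = R_base
    R_seg2 = R_base * R_hinge

    m1 = np.asarray(rig.mount1, dtype=float)
    m2 = np.asarray(rig.mount2, dtype=float)
    R_ws1 = R_seg1 * Rotation.from_matrix(m1).inv()
    R_ws2 = R_seg2 * Rotation.from_matrix(m2).inv()

    # world-frame angular velocity / acceleration of each segment
    axis_w = R_base.apply(axis)                       # hinge axis in world
    w2 = w1 + dtheta[:, None] * axis_w
    dw2 = (
        dw1
        + ddtheta[:, None] * axis_w
        + dtheta[:, None] * np.cross(w1, axis_w)
    )

    g_w = np.array([0.0, 0.0, -rig.gravity])

    def sensor_streams(R_seg, R_ws, lever, w, dw):
        r = R_seg.apply(np.asarray(lever, float))     # world lever arm
        vel = np.cross(w, r)
        acc = np.cross(dw, r) + np.cross(w, np.cross(w, r))
        gyro = R_ws.inv().apply(w)
        # d/dt(R^T w) = R^T(dw - w x w) = R^T dw
        dgyro = R_ws.inv().apply(dw)
        accel = R_ws.inv().apply(acc - g_w)
        return r, vel, gyro, dgyro, accel

    p1, v1, gyro1, dgyro1, accel1 = sensor_streams(R_seg1, R_ws1, rig.lever1, w1, dw1)
    p2, v2, gyro2, dgyro2, accel2 = sensor_streams(R_seg2, R_ws2, rig.lever2, w2, dw2)

    att1 = R_ws1.as_euler("ZYX")
    att2 = R_ws2.as_euler("ZYX")

    return SyntheticDataset(
        t=t,
        imu1=ImuSeries(t=t, accel=accel1, gyro=gyro1),
        imu2=ImuSeries(t=t, accel=accel2, gyro=gyro2),
        dgyro1=dgyro1,
        dgyro2=dgyro2,
        truth_angle=theta,
        truth_rate=dtheta,
        truth_att1=att1,
        truth_att2=att2,
        pos1=p1,
        vel1=v1,
        pos2=p2,
        vel2=v2,
        calibration=rig.truth_calibration(),
        rig=rig,
        motion=motion,
    )


def _soft_tissue_angle(t: np.ndarray, err: SensorErrorModel):
    """Damped-oscillation artifact angle and its analytic time derivative."""
    if err.st_retrigger_s:
        tau = np.mod(t, err.st_retrigger_s)
    else:
        tau = t
    A = err.st_amp_deg * DEG
    w = 2 * math.pi * err.st_freq_hz
    d = err.st_damping
    env = A * np.exp(-d * tau)
    delta = env * np.sin(w * tau)
    ddelta = env * (w * np.cos(w * tau) - d * np.sin(w * tau))
    return delta, ddelta


def corrupt(series: ImuSeries, err: SensorErrorModel) -> ImuSeries:
    """Apply the sensor error model; reproducible for a given seed.

    Order of effects: soft-tissue mount re-orientation (a physical effect on
    the clean signal), then constant biases, bias random walk (gyro), and
    white Gaussian noise.
    """
    rng = np.random.default_rng(err.seed)
    t = series.t
    accel = series.accel.copy()
    gyro = series.gyro.copy()

    if err.st_amp_deg != 0.0:
        delta, ddelta = _soft_tissue_angle(t, err)
        e = _unit(err.st_axis)
        E = Rotation.from_rotvec(np.outer(delta, e))
        # the perturbed mount sees rotated signals plus its own angular rate
        gyro = E.apply(gyro) + ddelta[:, None] * e
        accel = E.apply(accel)

    gyro = gyro + np.asarray(err.gyro_bias, float)
    accel = accel + np.asarray(err.accel_bias, float)

    if err.gyro_bias_walk_sd > 0:
        steps = rng.normal(
            0.0, err.gyro_bias_walk_sd * math.sqrt(series.dt), size=(len(series), 3)
        )
        gyro = gyro + np.cumsum(steps, axis=0)
    if err.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, err.gyro_noise_sd, size=gyro.shape)
    if err.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, err.accel_noise_sd, size=accel.shape)

    return ImuSeries(t=t.copy(), accel=accel, gyro=gyro)


def simulate_gps(
    t: np.ndarray,
    pos: np.ndarray,
    vel: np.ndarray,
    rate: float,
    pos_noise_sd: float = 1.0,
    vel_noise_sd: float = 0.1,
    seed: int = 0,
) -> GpsSeries:
    """Subsample a truth world trajectory into a noisy position/velocity fix stream."""
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    imu_rate = 1.0 / (t[1] - t[0])
    if rate > imu_rate + 1e-9:
        raise ValueError(f"GPS rate {rate} exceeds IMU rate {imu_rate}")
    step = max(1, int(round(imu_rate / rate)))
    idx = np.arange(0, len(t), step)
    rng = np.random.default_rng(seed)
    pos = np.asarray(pos, float)[idx]
    vel = np.asarray(vel, float)[idx]
    if pos_noise_sd > 0:
        pos = pos + rng.normal(0.0, pos_noise_sd, size=pos.shape)
    if vel_noise_sd > 0:
        vel = vel + rng.normal(0.0, vel_noise_sd, size=vel.shape)
    return GpsSeries(t=t[idx], pos=pos, vel=vel)


def simulate_translation(
    duration: float,
    rate: float = 100.0,
    amplitude: tuple[float, float, float] = (2.0, 1.5, 0.0),
    freq: tuple[float, float, float] = (0.1, 0.07, 0.0),
    gravity: float = GRAVITY,
):
    """Purely translational world trajectory with an identity-attitude IMU.

    Used to exercise the inertial/position-fix fusion filter: each axis moves
    as A sin(2 pi f t), with analytic velocity and acceleration.  The IMU is
    level and non-rotating, so its specific force is the world acceleration
    plus [0, 0, g].

    Returns
    -------
    dict with keys t, pos, vel, acc (world truth) and imu (ImuSeries).
    """
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    A = np.asarray(amplitude, float)
    w = 2 * math.pi * np.asarray(freq, float)
    pos = A * np.sin(np.outer(t, w))
    vel = A * w * np.cos(np.outer(t, w))
    acc = -A * w * w * np.sin(np.outer(t, w))
    accel = acc + np.array([0.0, 0.0, gravity])
    imu = ImuSeries(t=t, accel=accel, gyro=np.zeros((n, 3)))
    return {"t": t, "pos": pos, "vel": vel, "acc": acc, "imu": imu}


def with_seed(err: SensorErrorModel, seed: int) -> SensorErrorModel:
    """Copy of an error model with a different RNG seed."""
    return replace(err, seed=int(seed))
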