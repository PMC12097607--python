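"""Linear Kalman filtering and inertial/position-fix trajectory fusion.

The filter is the textbook linear minimum-variance recursion:

    predict:  x <- F x + B u,          P <- F P F' + Q
    update:   K  = P H' (H P H' + R)^-1
              x <- x + K (z - H x),    P <- (I - K H) P

The covariance update is evaluated in the Joseph-stabilized form
(I-KH) P (I-KH)' + K R K', which is algebraically identical for the optimal
gain but keeps P symmetric positive semidefinite in floating point.

Trajectory fusion runs one [position, velocity, acceleration] filter per world
axis: the prediction chain advances at the IMU rate, the world-frame
(gravity-compensated) acceleration enters as a high-rate measurement of the
acceleration state, and position/velocity fixes correct the chain at each fix
epoch.  Between fixes the filter runs prediction only, which is exactly the
dead-reckoning regime whose error the fixes bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .attitude import AttitudeTrace
from .rotations import GRAVITY, euler_to_matrix
from .sim import GpsSeries, ImuSeries

log = logging.getLogger(__name__)


class NumericalFilterError(RuntimeError):
    """Raised when an update step is numerically unsolvable."""


@dataclass
class LinearKalmanModel:
    """Matrices (F, B, H, Q, R) of a linear-Gaussian state-space model."""

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, float))
        self.H = np.atleast_2d(np.asarray(self.H, float))
        self.Q = np.atleast_2d(np.asarray(self.Q, float))
        self.R = np.atleast_2d(np.asarray(self.R, float))
        if self.B is not None:
            self.B = np.atleast_2d(np.asarray(self.B, float))
        n = self.F.shape[0]
        m = self.H.shape[0]
        if self.F.shape != (n, n) or self.Q.shape != (n, n):
            raise ValueError("F and Q must be square and consistent")
        if self.H.shape[1] != n or self.R.shape != (m, m):
            raise ValueError("H/R dimensions inconsistent with state size")
        for M, name in ((self.Q, "Q"), (self.R, "R")):
            if not np.allclose(M, M.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-9:
                raise ValueError(f"{name} must be positive semidefinite")


@dataclass
class KalmanState:
    """State estimate and covariance; ``gain`` holds the last update's K."""

    x: np.ndarray
    P: np.ndarray
    gain: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, float))
        self.P = np.atleast_2d(np.asarray(self.P, float))
        n = self.x.shape[0]
        if self.P.shape != (n, n):
            raise ValueError(f"P shape {self.P.shape} inconsistent with x ({n})")


def kf_predict(
    state: KalmanState, model: LinearKalmanModel, u: np.ndarray | None = None
) -> KalmanState:
    """Time update: x <- Fx + Bu, P <- FPF' + Q (re-symmetrized)."""
    x = model.F @ state.x
    if u is not None:
        if model.B is None:
            raise ValueError("control input given but model has no B matrix")
        x = x + (model.B @ np.atleast_1d(np.asarray(u, float))).ravel()
    P = model.F @ state.P @ model.F.T + model.Q
    P = 0.5 * (P + P.T)
    return KalmanState(x=x, P=P)


def kf_update(state: KalmanState, model: LinearKalmanModel, z) -> KalmanState:
    """Measurement update with gain K = PH'(HPH' + R)^-1.

    The returned state records K in ``gain`` for inspection — the gain is what
    sets the balance between trusting the model and trusting the measurement.
    """
    z = np.atleast_1d(np.asarray(z, float))
    H, R, P = model.H, model.R, state.P
    S = H @ P @ H.T + R
    try:
        K = np.linalg.solve(S.T, (P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalFilterError(
            f"singular innovation covariance (cond S = {np.linalg.cond(S):.3g})"
        ) from exc
    x = state.x + K @ (z - H @ state.x)
    IKH = np.eye(P.shape[0]) - K @ H
    P_new = IKH @ P @ IKH.T + K @ R @ K.T  # Joseph form of (I-KH)P
    P_new = 0.5 * (P_new + P_new.T)
    return KalmanState(x=x, P=P_new, gain=K)


def dead_reckon(
    t: np.ndarray, accel: np.ndarray, p0=0.0, v0=0.0
) -> np.ndarray:
    """Trapezoidal double integration of world acceleration to position.

    The uncorrected inertial baseline: a constant accelerometer bias eps
    produces the classic quadratic position drift eps t^2 / 2.
    """
    t = np.asarray(t, float)
    accel = np.asarray(accel, float)
    v = v0 + cumulative_trapezoid(accel, t, axis=0, initial=0.0)
    p = p0 + cumulative_trapezoid(v, t, axis=0, initial=0.0)
    return p


@dataclass(frozen=True)
class FusionConfig:
    """Per-axis [p, v, a] fusion filter parameters.

    q : white-noise-jerk spectral density driving the acceleration state,
        (m/s^2)^2 per second; the discrete Q couples it into all three states.
    r_pos, r_vel : fix measurement variances, m^2 and (m/s)^2.  Position fixes
        are low-rate and coarse, so r_pos is large relative to the IMU noise.
    r_acc : variance of the high-rate world-acceleration measurement.  The
        default is deliberately inflated well above the white-noise level:
        accelerometer bias is slowly varying, not white, and a filter that
        trusts the accelerometer at its noise floor tracks the bias into a
        steady-state position lag.
    half_dt2 : use the full constant-acceleration transition with the 1/2 dt^2
        position term instead of the default bidiagonal chain.
    """

    q: float = 0.1
    r_pos: float = 1.0
    r_vel: float = 0.01
    r_acc: float = 0.25
    half_dt2: bool = False
    gravity: float = GRAVITY


def transition_matrix(dt: float, half_dt2: bool = False) -> np.ndarray:
    """Constant-acceleration state transition for the [p, v, a] chain."""
    F = np.array([[1.0, dt, 0.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    if half_dt2:
        F[0, 2] = 0.5 * dt * dt
    return F


def jerk_process_noise(q: float, dt: float) -> np.ndarray:
    """Discrete white-noise-jerk covariance for the [p, v, a] chain."""
    return q * np.array(
        [
            [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
            [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
            [dt**3 / 6.0, dt**2 / 2.0, dt],
        ]
    )


def world_accel(
    imu: ImuSeries, attitudes: AttitudeTrace, gravity: float = GRAVITY
) -> np.ndarray:
    """Rotate specific force to the world frame and remove gravity."""
    if len(attitudes) != len(imu):
        raise ValueError("attitude trace length does not match IMU series")
    R = euler_to_matrix(attitudes.yaw, attitudes.pitch, attitudes.roll)
    a_w = np.einsum("nij,nj->ni", R, imu.accel)
    a_w[:, 2] -= gravity
    return a_w


def fuse_imu_gps(
    imu: ImuSeries,
    attitudes: AttitudeTrace,
    gps: GpsSeries | None,
    cfg: FusionConfig | None = None,
):
    """Fuse inertial dead reckoning with position/velocity fixes.

    Runs three independent [p, v, a] filters (one per world axis).  Returns a
    dict with t, pos, vel (fused trace) and an innovation log (one row per fix
    epoch: t, axis, innovation, gain norm).

    With an empty/None fix stream the filter degenerates to (filtered) dead
    reckoning, with a warning.
    """
    cfg = cfg or FusionConfig()
    a_w = world_accel(imu, attitudes, cfg.gravity)
    n = len(imu)
    dt = imu.dt

    F = transition_matrix(dt, cfg.half_dt2)
    Q = jerk_process_noise(cfg.q, dt)
    model_pred = LinearKalmanModel(F=F, H=np.eye(3), Q=Q, R=np.eye(3))
    H_acc = np.array([[0.0, 0.0, 1.0]])
    R_acc = np.array([[cfg.r_acc]])
    model_acc = LinearKalmanModel(F=F, H=H_acc, Q=Q, R=R_acc)
    H_fix = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    R_fix = np.diag([cfg.r_pos, cfg.r_vel])
    model_fix = LinearKalmanModel(F=F, H=H_fix, Q=Q, R=R_fix)

    if gps is None or len(gps) == 0:
        log.warning("fuse_imu_gps: no fixes; output degenerates to dead reckoning")
        gps_idx: dict[int, int] = {}
        x0 = np.zeros((3, 3))
    else:
        # align each fix epoch to the nearest IMU sample (no interpolation)
        idx = np.clip(np.round((gps.t - imu.t[0]) / dt).astype(int), 0, n - 1)
        if gps.t[0] < imu.t[0] - 1e-9 or gps.t[-1] > imu.t[-1] + 1e-9:
            raise ValueError("GPS timestamps fall outside the IMU time range")
        gps_idx = {int(k): int(i) for i, k in enumerate(idx)}
        x0 = np.column_stack([gps.pos[0], gps.vel[0], a_w[0]])  # (3 axes, 3 states)

    states = [KalmanState(x=x0[ax], P=np.eye(3)) for ax in range(3)]
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    innovations = []
    for k in range(n):
        for ax in range(3):
            s = states[ax]
            if k > 0:
                s = kf_predict(s, model_pred)
            s = kf_update(s, model_acc, a_w[k, ax])
            if k in gps_idx:
                i = gps_idx[k]
                z = np.array([gps.pos[i, ax], gps.vel[i, ax]])
                innov = z - model_fix.H @ s.x
                s = kf_update(s, model_fix, z)
                innovations.append(
                    (imu.t[k], ax, float(innov[0]), float(np.linalg.norm(s.gain)))
                )
            states[ax] = s
            pos[k, ax] = s.x[0]
            vel[k, ax] = s.x[1]
    return {"t": imu.t, "pos": pos, "vel": vel, "innovations": innovations}
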