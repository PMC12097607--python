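"""Hinge-joint self-calibration and joint-angle estimation from two IMUs.

For a one-degree-of-freedom joint, the angular velocities of the two segments
differ only by the hinge rate about the joint axis.  Two kinematic constraints
follow, each usable for self-calibration without any manual measurement:

* axis constraint — the projections of the two angular rates onto the plane
  normal to the joint axis have equal length at every instant:
  ||g1 x j1|| = ||g2 x j2||.  Minimizing the squared residual over the unit
  sphere pair (j1, j2) identifies the hinge axis in each sensor frame.
* joint-center constraint — the acceleration of the joint center is the same
  seen from both sensors: ||a1 - Gamma_g1(o1)|| = ||a2 - Gamma_g2(o2)||, where
  Gamma_g(o) = g x (g x o) + dg/dt x o is the centripetal + tangential
  acceleration of a point at lever arm o.  Minimizing over (o1, o2) locates
  the joint center in each sensor frame.

Joint angle comes from three complementary routes: integration of the axial
angular-rate difference (drifts), the angle between joint-plane projections of
the lever-arm-corrected accelerations (noisy but absolute), and their
recursive complementary fusion; a fourth route aligns windowed gravity
directions by SVD and reads the hinge angle off the relative rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .attitude import StillnessConfig, detect_still
from .rotations import best_fit_rotation, hinge_angle_from_relative, UnidentifiableRotationError
from .sim import ImuSeries

log = logging.getLogger(__name__)

RAD2DEG = 180.0 / np.pi


class InsufficientExcitationError(ValueError):
    """Motion does not excite the parameters being estimated."""


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class JointDataset:
    """Synchronized two-sensor samples {a1, a2, g1, g2, dg1, dg2}."""

    t: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    dg1: np.ndarray
    dg2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("a1", "a2", "g1", "g2", "dg1", "dg2"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, 3)")
        dt = np.diff(self.t)
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("JointDataset requires a uniform sampling period")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class JointCalibration:
    """Estimated sensor-frame joint axes, lever arms, and stage residuals."""

    j1: np.ndarray
    j2: np.ndarray
    o1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    o2: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_residual_rms: float = 0.0
    center_residual_rms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("j1", "j2"):
            j = np.asarray(getattr(self, name), float)
            if abs(np.linalg.norm(j) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
            setattr(self, name, j)
        self.o1 = np.asarray(self.o1, float)
        self.o2 = np.asarray(self.o2, float)

    def to_dict(self) -> dict:
        return {
            "j1": self.j1.tolist(),
            "j2": self.j2.tolist(),
            "o1": self.o1.tolist(),
            "o2": self.o2.tolist(),
            "axis_residual_rms": self.axis_residual_rms,
            "center_residual_rms": self.center_residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointCalibration":
        return cls(
            j1=np.asarray(d["j1"], float),
            j2=np.asarray(d["j2"], float),
            o1=np.asarray(d["o1"], float),
            o2=np.asarray(d["o2"], float),
            axis_residual_rms=float(d.get("axis_residual_rms", 0.0)),
            center_residual_rms=float(d.get("center_residual_rms", 0.0)),
        )


@dataclass
class AngleTrace:
    """Time-stamped joint angle (radians) with a source tag."""

    t: np.ndarray
    angle: np.ndarray
    source: str = "fused"  # gyro | accel | fused | svd
    flags: np.ndarray | None = None  # samples carried forward / degenerate

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.angle = np.asarray(self.angle, float)
        if self.angle.shape != self.t.shape:
            raise ValueError("angle/t length mismatch")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("non-finite angles")

    def degrees(self) -> np.ndarray:
        return self.angle * RAD2DEG

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class RomSummary:
    """Range of motion: min/max/range of a joint-angle trace, degrees."""

    min_deg: float
    max_deg: float

    @property
    def range_deg(self) -> float:
        return self.max_deg - self.min_deg


# --------------------------------------------------------------------------
# Dataset assembly
# --------------------------------------------------------------------------


def central_difference(y: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference time derivative along axis 0.

    Five-point (fourth-order) central stencil in the interior, falling back
    to three-point/one-sided differences near the ends.  Exact for linear
    ramps; the higher-order interior stencil keeps the truncation bias of the
    derivative well below the sensitivity of the joint-center cost.
    """
    y = np.asarray(y, float)
    d = np.gradient(y, dt, axis=0)
    if len(y) >= 5:
        d[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12.0 * dt)
    return d


def build_joint_dataset(imu1: ImuSeries, imu2: ImuSeries) -> JointDataset:
    """Assemble the synchronized dataset; angular accelerations by central
    differences of the gyro streams."""
    if len(imu1) != len(imu2) or not np.allclose(imu1.t, imu2.t, atol=1e-9):
        raise ValueError("IMU streams must share identical timestamps; resample first")
    dg1 = central_difference(imu1.gyro, imu1.dt)
    dg2 = central_difference(imu2.gyro, imu2.dt)
    return JointDataset(
        t=imu1.t, a1=imu1.accel, a2=imu2.accel,
        g1=imu1.gyro, g2=imu2.gyro, dg1=dg1, dg2=dg2,
    )


# --------------------------------------------------------------------------
# Axis calibration
# --------------------------------------------------------------------------


def _sph_to_unit(az: float, el: float) -> np.ndarray:
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def axis_residual(g1: np.ndarray, g2: np.ndarray, j1, j2) -> np.ndarray:
    """Axis-constraint residual ||g1 x j1|| - ||g2 x j2|| per sample."""
    j1 = np.asarray(j1, float)
    j2 = np.asarray(j2, float)
    for j, name in ((j1, "j1"), (j2, "j2")):
        if abs(np.linalg.norm(j) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a unit vector")
    g1 = np.atleast_2d(np.asarray(g1, float))
    g2 = np.atleast_2d(np.asarray(g2, float))
    r = np.linalg.norm(np.cross(g1, j1), axis=1) - np.linalg.norm(
        np.cross(g2, j2), axis=1
    )
    return r if r.size > 1 else float(r[0])


_AXIS_STARTS = [
    np.array([sx, sy, sz]) / np.sqrt(3.0)
    for sx in (1.0, -1.0) for sy in (1.0, -1.0) for sz in (1.0, -1.0)
]


def estimate_joint_axes(
    W: JointDataset, excitation_floor: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Identify the hinge axis in both sensor frames from the axis constraint.

    Levenberg-Marquardt on a spherical (azimuth, elevation) parametrization of
    each axis, restarted from eight deterministic directions (cube corners);
    the best final cost wins.  The sign of j1 is fixed by the majority sign of
    g1 . j1 over the record, and the sign of j2 by maximizing the correlation
    of the two axial rate projections, making the hinge-rate difference
    g1 . j1 - g2 . j2 a consistent flexion-rate convention across runs.

    Returns (j1, j2, residual RMS).

    Raises
    ------
    InsufficientExcitationError
        If either sensor's RMS angular rate is below ``excitation_floor``.
    """
    for g, name in ((W.g1, "sensor 1"), (W.g2, "sensor 2")):
        rms = float(np.sqrt(np.mean(np.sum(g * g, axis=1))))
        if rms < excitation_floor:
            raise InsufficientExcitationError(
                f"{name} RMS angular rate {rms:.4g} rad/s below "
                f"{excitation_floor}: joint axis unidentifiable"
            )

    def residual(p):
        j1 = _sph_to_unit(p[0], p[1])
        j2 = _sph_to_unit(p[2], p[3])
        return np.linalg.norm(np.cross(W.g1, j1), axis=1) - np.linalg.norm(
            np.cross(W.g2, j2), axis=1
        )

    best = None
    for d in _AXIS_STARTS:
        az = np.arctan2(d[1], d[0])
        el = np.arcsin(d[2])
        p0 = np.array([az, el, az, el])
        sol = least_squares(
            residual, p0, method="lm", gtol=1e-10, xtol=1e-12, max_nfev=200 * 5
        )
        if best is None or sol.cost < best.cost:
            best = sol
    j1 = _sph_to_unit(best.x[0], best.x[1])
    j2 = _sph_to_unit(best.x[2], best.x[3])

    # Deterministic sign convention.  The constraint is even in each axis, so
    # orient the pair consistently: rotating j2 into sensor-1 coordinates via
    # the relative orientation (Kabsch on paired gravity directions, which is
    # invariant to the hinge angle) must align it with j1.  The overall pair
    # sign (the flexion direction) is fixed by the majority sign of the axial
    # rate difference's largest excursions.
    try:
        sub = slice(0, len(W), max(1, len(W) // 400))
        v1 = W.a1[sub] / np.linalg.norm(W.a1[sub], axis=1, keepdims=True)
        v2 = W.a2[sub] / np.linalg.norm(W.a2[sub], axis=1, keepdims=True)
        R_rel = best_fit_rotation(v2, v1)
        if float((R_rel @ j2) @ j1) < 0:
            j2 = -j2
    except UnidentifiableRotationError:
        p1, p2 = W.g1 @ j1, W.g2 @ j2
        if float(p1 @ p2) < 0:
            j2 = -j2
    diff = W.g1 @ j1 - W.g2 @ j2
    big = np.abs(diff) > 0.5 * np.max(np.abs(diff))
    if np.sum(np.sign(diff[big])) < 0:
        j1, j2 = -j1, -j2
    rms = float(np.sqrt(2.0 * best.cost / len(W)))
    return j1, j2, rms


# --------------------------------------------------------------------------
# Joint-center calibration
# --------------------------------------------------------------------------


def rotational_accel(g: np.ndarray, dg: np.ndarray, o) -> np.ndarray:
    """Gamma_g(o) = g x (g x o) + dg x o: acceleration of the point at lever o."""
    g = np.atleast_2d(np.asarray(g, float))
    dg = np.atleast_2d(np.asarray(dg, float))
    o = np.asarray(o, float)
    out = np.cross(g, np.cross(g, o[None, :])) + np.cross(dg, o[None, :])
    return out if out.shape[0] > 1 else out[0]


def center_residual(a1, g1, dg1, a2, g2, dg2, o1, o2) -> np.ndarray:
    """Joint-center residual ||a1 - Gamma1(o1)|| - ||a2 - Gamma2(o2)|| per sample."""
    c1 = np.atleast_2d(a1) - np.atleast_2d(rotational_accel(g1, dg1, o1))
    c2 = np.atleast_2d(a2) - np.atleast_2d(rotational_accel(g2, dg2, o2))
    r = np.linalg.norm(c1, axis=1) - np.linalg.norm(c2, axis=1)
    return r if r.size > 1 else float(r[0])


_CENTER_STARTS = [np.zeros(6)] + [
    np.concatenate([s * 0.05 * e, s * 0.05 * e])
    for e in np.eye(3) for s in (1.0, -1.0)
]


def lever_gauge(o1, o2, j1, j2) -> tuple[np.ndarray, np.ndarray]:
    """Canonical representative of the lever-arm gauge orbit.

    For a hinge, every point on the axis is a joint center, so (o1, o2) is
    identifiable only up to a common shift along (j1, j2).  This picks the
    representative with zero mean axial offset, o1.j1 + o2.j2 = 0.
    """
    o1 = np.asarray(o1, float)
    o2 = np.asarray(o2, float)
    s = -(o1 @ np.asarray(j1, float) + o2 @ np.asarray(j2, float)) / 2.0
    return o1 + s * np.asarray(j1, float), o2 + s * np.asarray(j2, float)


def estimate_joint_centers(
    W: JointDataset,
    j1=None,
    j2=None,
    excitation_floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Locate the joint center in both sensor frames from the center constraint.

    Levenberg-Marquardt over (o1, o2) from the origin plus six axis-aligned
    5 cm starts.  Requires varying angular acceleration: at constant rate
    (dg = 0) the tangential term vanishes and the levers are unidentifiable.
    If the joint axes are supplied, the result is returned in the canonical
    gauge of :func:`lever_gauge` (the axial position of a hinge's center is a
    gauge freedom the data cannot fix).

    Returns (o1, o2, residual RMS).
    """
    dd = float(np.sqrt(np.mean(np.sum(W.dg1**2, axis=1)))) + float(
        np.sqrt(np.mean(np.sum(W.dg2**2, axis=1)))
    )
    if dd < excitation_floor:
        raise InsufficientExcitationError(
            f"angular-acceleration RMS {dd:.4g} rad/s^2 below {excitation_floor}: "
            "joint center unidentifiable (constant-rate or still record)"
        )

    def residual(p):
        return center_residual(
            W.a1, W.g1, W.dg1, W.a2, W.g2, W.dg2, p[:3], p[3:]
        )

    best = None
    for p0 in _CENTER_STARTS:
        sol = least_squares(
            residual, p0, method="lm", gtol=1e-10, xtol=1e-12, max_nfev=200 * 7
        )
        if best is None or sol.cost < best.cost:
            best = sol
    o1, o2 = best.x[:3], best.x[3:]
    if j1 is not None and j2 is not None:
        o1, o2 = lever_gauge(o1, o2, j1, j2)
    rms = float(np.sqrt(2.0 * best.cost / len(W)))
    return o1, o2, rms


def calibrate(W: JointDataset) -> JointCalibration:
    """Run both self-calibration stages (axes, then joint centers)."""
    j1, j2, ar = estimate_joint_axes(W)
    o1, o2, cr = estimate_joint_centers(W, j1, j2)
    return JointCalibration(
        j1=j1, j2=j2, o1=o1, o2=o2, axis_residual_rms=ar, center_residual_rms=cr
    )


# --------------------------------------------------------------------------
# Joint-angle estimators
# --------------------------------------------------------------------------


def joint_angle_gyro(W: JointDataset, j1, j2, alpha0: float = 0.0) -> AngleTrace:
    """Integrated axial angular-rate difference (trapezoidal rule).

    alpha_f(t) = alpha0 + integral of (g1 . j1 - g2 . j2).  Unbiased in the
    short term but drifts under uncompensated gyro bias; a bias appearing
    identically in both axial projections cancels exactly (common-mode
    rejection), while a single-sensor bias drifts at exactly its axial
    component.
    """
    rate = W.g1 @ np.asarray(j1, float) - W.g2 @ np.asarray(j2, float)
    ang = alpha0 + cumulative_trapezoid(rate, W.t, initial=0.0)
    return AngleTrace(t=W.t, angle=ang, source="gyro")


def _plane_basis(j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane normal to j."""
    j = np.asarray(j, float)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(j)))] = 1.0
    x = e - (e @ j) * j
    x /= np.linalg.norm(x)
    y = np.cross(j, x)
    return x, y


def joint_angle_accel(
    W: JointDataset,
    calib: JointCalibration,
    alpha0: float = 0.0,
    still_interval=None,
    min_proj: float = 1.0,
) -> AngleTrace:
    """Joint angle from lever-arm-corrected accelerations.

    Each sensor's acceleration is shifted to the joint center
    (a_i - Gamma_gi(o_i)), projected onto the plane normal to its joint axis,
    and converted to an in-plane phase; the phase difference tracks the joint
    angle.  The trace is anchored so that its mean over ``still_interval``
    (default: the first detected still period, else the first sample) equals
    ``alpha0``.  Samples whose projection is shorter than ``min_proj`` m/s^2
    (acceleration nearly parallel to the axis) are flagged and carried forward.
    """
    at1 = W.a1 - rotational_accel(W.g1, W.dg1, calib.o1)
    at2 = W.a2 - rotational_accel(W.g2, W.dg2, calib.o2)
    x1, y1 = _plane_basis(calib.j1)
    x2, y2 = _plane_basis(calib.j2)
    p1 = np.column_stack([at1 @ x1, at1 @ y1])
    p2 = np.column_stack([at2 @ x2, at2 @ y2])
    n1 = np.linalg.norm(p1, axis=1)
    n2 = np.linalg.norm(p2, axis=1)
    ok = (n1 > min_proj) & (n2 > min_proj)
    phi1 = np.arctan2(p1[:, 1], p1[:, 0])
    phi2 = np.arctan2(p2[:, 1], p2[:, 0])
    # the apparent in-plane phase of a world-fixed direction advances at
    # -(g . j) in each sensor, so phi2 - phi1 integrates like g1.j1 - g2.j2,
    # matching the gyro route's sign convention
    raw = np.unwrap(phi2 - phi1)
    # carry degenerate samples forward
    if not ok.all():
        idx = np.where(ok, np.arange(len(ok)), -1)
        np.maximum.accumulate(idx, out=idx)
        first = np.argmax(ok) if ok.any() else 0
        idx[idx < 0] = first
        raw = raw[idx]
        log.warning(
            "joint_angle_accel: %d/%d samples with projection < %.2g m/s^2 carried forward",
            int((~ok).sum()), len(ok), min_proj,
        )
    if still_interval is None:
        s, e = 0, max(1, min(len(raw), 10))
    else:
        s, e = int(still_interval[0]), int(still_interval[1])
    ang = raw - np.mean(raw[s:e]) + alpha0
    return AngleTrace(t=W.t, angle=ang, source="accel", flags=~ok)


def fuse_joint_angles(
    accel_trace: AngleTrace, gyro_trace: AngleTrace, coefficient: float = 0.98
) -> AngleTrace:
    """Recursive complementary blend of the two joint-angle routes.

    alpha(t) = c (alpha(t - dt) + d alpha_f) + (1 - c) alpha_s(t): the gyro
    supplies the high-frequency increments, the accelerometer route the
    drift-free low-frequency reference.  c = 1 returns the integrated-gyro
    trace, c = 0 the accelerometer trace.
    """
    if len(accel_trace) != len(gyro_trace) or not np.allclose(
        accel_trace.t, gyro_trace.t
    ):
        raise ValueError("traces must share timestamps")
    if not 0.0 <= coefficient <= 1.0:
        raise ValueError("coefficient must be in [0, 1]")
    c = coefficient
    n = len(gyro_trace)
    out = np.zeros(n)
    out[0] = c * gyro_trace.angle[0] + (1 - c) * accel_trace.angle[0]
    dg = np.diff(gyro_trace.angle)
    for i in range(1, n):
        out[i] = c * (out[i - 1] + dg[i - 1]) + (1 - c) * accel_trace.angle[i]
    return AngleTrace(t=gyro_trace.t, angle=out, source="fused")


def joint_angle_svd(
    imu1: ImuSeries,
    imu2: ImuSeries,
    window_s: float = 1.0,
    alpha0: float = 0.0,
    calibration: JointCalibration | None = None,
) -> AngleTrace:
    """Hinge angle from windowed SVD alignment of gravity directions.

    Within each sliding window the unit acceleration vectors of the two
    sensors are treated as paired observations of common world directions; the
    best-fit rotation mapping sensor-2 pairs onto sensor-1 is the relative
    sensor orientation, and its X-Euler angle (atan2 of the (3,2)/(3,3)
    entries) is the hinge angle.  With a calibration, each acceleration is
    first shifted to the joint center (a - Gamma_g(o)), which removes the
    lever-arm dynamics and leaves clean gravity directions.  Windows whose
    directions are collinear (no attitude variety) are flagged and carried
    forward.  The trace is anchored to ``alpha0`` at the first valid window,
    so it reports angle relative to the initial posture.

    The window model assumes the joint angle is quasi-static within each
    window (the relative orientation the pairs share is treated as constant);
    fast flexion inside a window biases that window's estimate.
    """
    if len(imu1) != len(imu2) or not np.allclose(imu1.t, imu2.t):
        raise ValueError("IMU streams must share timestamps")
    n = len(imu1)
    w = max(2, int(round(window_s * imu1.rate)))
    a1, a2 = imu1.accel, imu2.accel
    if calibration is not None:
        W = build_joint_dataset(imu1, imu2)
        a1 = a1 - rotational_accel(W.g1, W.dg1, calibration.o1)
        a2 = a2 - rotational_accel(W.g2, W.dg2, calibration.o2)
    v1 = a1 / np.linalg.norm(a1, axis=1, keepdims=True)
    v2 = a2 / np.linalg.norm(a2, axis=1, keepdims=True)
    half = w // 2
    raw = np.full(n, np.nan)
    for c in range(half, n - (w - half)):
        lo, hi = c - half, c - half + w
        try:
            R = best_fit_rotation(v2[lo:hi], v1[lo:hi])
        except UnidentifiableRotationError:
            continue
        raw[c] = hinge_angle_from_relative(R)
    valid = np.isfinite(raw)
    if not valid.any():
        raise InsufficientExcitationError(
            "every window is degenerate: no attitude variety for the SVD route"
        )
    flags = ~valid
    # unwrap over valid samples, then carry forward/backward
    vi = np.where(valid)[0]
    raw[vi] = np.unwrap(raw[vi])
    filled = np.interp(np.arange(n), vi, raw[vi])
    ang = filled - raw[vi[0]] + alpha0
    if flags.any():
        log.warning(
            "joint_angle_svd: %d/%d degenerate windows carried forward",
            int(flags.sum()), n,
        )
    return AngleTrace(t=imu1.t, angle=ang, source="svd", flags=flags)


def range_of_motion(trace: AngleTrace) -> RomSummary:
    """Min/max/range of a joint-angle trace, in degrees."""
    if len(trace) == 0:
        raise ValueError("empty angle trace")
    deg = trace.degrees()
    return RomSummary(min_deg=float(np.min(deg)), max_deg=float(np.max(deg)))


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------


def _first_joint_still(
    imu1: ImuSeries, imu2: ImuSeries, still_cfg: StillnessConfig | None = None
):
    """First interval during which BOTH sensors are still (joint at rest).

    A stationary proximal segment is still even while the joint flexes, so
    anchoring on a single sensor's stillness would average over motion.
    """
    try:
        s1 = detect_still(imu1, still_cfg)
        s2 = detect_still(imu2, still_cfg)
    except ValueError:
        return None
    for a0, a1 in s1:
        for b0, b1 in s2:
            lo, hi = max(a0, b0), min(a1, b1)
            if hi > lo:
                return (lo, hi)
    return None


def joint_angle_pipeline(
    imu1: ImuSeries,
    imu2: ImuSeries,
    calibration: JointCalibration | None = None,
    coefficient: float = 0.98,
    lowpass_hz: float | None = 4.0,
    denoise: bool = True,
    alpha0: float = 0.0,
    still_cfg: StillnessConfig | None = None,
):
    """Measurement pipeline: preprocess -> (calibrate) -> angle routes -> fusion.

    Preprocessing wavelet-denoises and low-passes both streams (the joint
    motion band sits well below the soft-tissue oscillation band).  If no
    calibration is supplied, both self-calibration stages run on the same
    record.  Returns a dict with the calibration and the gyro/accel/fused
    angle traces.
    """
    from .denoise import denoise_imu, lowpass_imu  # local import to avoid cycle

    proc1, proc2 = imu1, imu2
    if denoise:
        proc1 = denoise_imu(proc1, channels="all")
        proc2 = denoise_imu(proc2, channels="all")
    if lowpass_hz is not None:
        proc1 = lowpass_imu(proc1, lowpass_hz)
        proc2 = lowpass_imu(proc2, lowpass_hz)
    W = build_joint_dataset(proc1, proc2)
    calib = calibration or calibrate(W)
    still = _first_joint_still(proc1, proc2, still_cfg)
    gyro = joint_angle_gyro(W, calib.j1, calib.j2, alpha0=alpha0)
    accel = joint_angle_accel(W, calib, alpha0=alpha0, still_interval=still)
    fused = fuse_joint_angles(accel, gyro, coefficient=coefficient)
    return {"calibration": calib, "gyro": gyro, "accel": accel, "fused": fused}
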