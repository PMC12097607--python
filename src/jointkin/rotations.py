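"""Rotation matrices and ZYX Euler-angle kinematics.

Attitude is parametrized throughout the package by intrinsic ZYX Euler angles
(yaw about Z, then pitch about Y, then roll about X), the convention used by
strapdown IMU attitude pipelines.  All angles are in radians; degrees appear
only at file/CLI boundaries.

The body (sensor) frame convention: for attitude (yaw a, pitch b, roll c), the
rotation taking body-frame vectors into the world frame is

    R_wb = Rz(a) @ Ry(b) @ Rx(c)

so a world-frame vector u reads in the body frame as R_wb.T @ u.  A static
accelerometer therefore measures R_wb.T @ [0, 0, g].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAVITY = 9.81
"""Default gravitational acceleration magnitude, m/s^2."""

_AXES = {"x": 0, "y": 1, "z": 2, "X": 0, "Y": 1, "Z": 2}


class SingularAttitudeError(ValueError):
    """Pitch at/near +-90 deg: the ZYX decomposition is not unique."""


class UnobservableAttitudeError(ValueError):
    """Accelerometer vector too small to define an attitude."""


class UnidentifiableRotationError(ValueError):
    """Vector pairs do not constrain a unique best-fit rotation."""


@dataclass(frozen=True)
class EulerZYX:
    """ZYX Euler angles: yaw (Z), pitch (Y), roll (X), radians.

    Pitch is restricted to the open interval (-pi/2, pi/2) so that the
    decomposition is unique; singular configurations are rejected.
    """

    yaw: float
    pitch: float
    roll: float

    def __post_init__(self) -> None:
        vals = (self.yaw, self.pitch, self.roll)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Euler angles: {vals}")
        if abs(self.pitch) >= np.pi / 2:
            raise SingularAttitudeError(
                f"|pitch| = {abs(self.pitch):.6f} >= pi/2: singular ZYX attitude"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        """Body-to-world rotation Rz(yaw) @ Ry(pitch) @ Rx(roll)."""
        return (
            elemental_rotation("z", self.yaw)
            @ elemental_rotation("y", self.pitch)
            @ elemental_rotation("x", self.roll)
        )


def elemental_rotation(axis: str, angle: float) -> np.ndarray:
    """Right-handed rotation matrix about a coordinate axis.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
    angle : float
        Rotation angle in radians.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}")
    if not np.isfinite(angle):
        raise ValueError(f"non-finite rotation angle: {angle}")
    c, s = np.cos(angle), np.sin(angle)
    if _AXES[axis] == 0:
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if _AXES[axis] == 1:
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about an arbitrary unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True if R is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def body_gravity(attitude: EulerZYX, g: float = GRAVITY) -> np.ndarray:
    """Ideal static accelerometer reading for a given attitude.

    Returns R_wb.T @ [0, 0, g]: gravity expressed in the body frame.  Yaw has
    no effect (gravity is invariant under rotation about the vertical), which
    is why the accelerometer cannot observe heading.
    """
    return attitude.rotation_matrix().T @ np.array([0.0, 0.0, float(g)])


def accel_roll_pitch(s: np.ndarray, eps: float = 0.1) -> tuple[float, float]:
    """Roll and pitch from a static accelerometer sample.

    roll  = atan2(sy, sz)
    pitch = -atan(sx / sqrt(sy^2 + sz^2))

    atan2 preserves the roll quadrant; the pitch denominator is nonnegative,
    bounding pitch to (-pi/2, pi/2).  Yaw is unobservable and not returned.

    Raises
    ------
    UnobservableAttitudeError
        If ``|s| <= eps`` (free fall / degenerate sample).
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3,) or not np.all(np.isfinite(s)):
        raise ValueError(f"expected finite 3-vector, got {s!r}")
    if np.linalg.norm(s) <= eps:
        raise UnobservableAttitudeError(
            f"|accel| = {np.linalg.norm(s):.4g} <= {eps}: attitude unobservable"
        )
    roll = float(np.arctan2(s[1], s[2]))
    pitch = float(-np.arctan(s[0] / np.hypot(s[1], s[2])))
    return roll, pitch


def euler_rates_to_body_rates(attitude: EulerZYX, euler_rates) -> np.ndarray:
    """Map ZYX Euler-angle rates (da/dt, db/dt, dc/dt) to body angular rates.

    [fx, fy, fz]^T = GX @ GY @ [0,0,da/dt]^T + GX @ [0,db/dt,0]^T + [dc/dt,0,0]^T

    where GX, GY express each partial rotation's axis in the body frame
    (GX = Rx(-roll), GY = Ry(-pitch)).
    """
    da, db, dc = np.asarray(euler_rates, dtype=float)
    gx = elemental_rotation("x", -attitude.roll)
    gy = elemental_rotation("y", -attitude.pitch)
    return (
        gx @ gy @ np.array([0.0, 0.0, da])
        + gx @ np.array([0.0, db, 0.0])
        + np.array([dc, 0.0, 0.0])
    )


def body_rates_to_euler_rates(
    attitude: EulerZYX, omega_body, pitch_margin: float = 1e-3
) -> np.ndarray:
    """Inverse Euler-rate kinematics: body rates -> (da/dt, db/dt, dc/dt).

    Exact inverse of :func:`euler_rates_to_body_rates`:

        da/dt = (wy sin c + wz cos c) / cos b
        db/dt =  wy cos c - wz sin c
        dc/dt =  wx + (wy sin c + wz cos c) tan b

    Raises
    ------
    SingularAttitudeError
        If ``|pitch| >= pi/2 - pitch_margin`` (gimbal lock).
    """
    if abs(attitude.pitch) >= np.pi / 2 - pitch_margin:
        raise SingularAttitudeError(
            f"pitch {attitude.pitch:.4f} within {pitch_margin} of gimbal lock"
        )
    wx, wy, wz = np.asarray(omega_body, dtype=float)
    sc, cc = np.sin(attitude.roll), np.cos(attitude.roll)
    cb, tb = np.cos(attitude.pitch), np.tan(attitude.pitch)
    da = (wy * sc + wz * cc) / cb
    db = wy * cc - wz * sc
    dc = wx + (wy * sc + wz * cc) * tb
    return np.array([da, db, dc])


def best_fit_rotation(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing sum ||R v1_i - v2_i||^2 (Wahba/Kabsch).

    Solved by SVD of the correlation matrix with the standard determinant
    correction diag(1, 1, sign det), so a reflection is never returned.

    Parameters
    ----------
    v1, v2 : (n, 3) arrays of paired vectors, n >= 2, spanning a plane.

    Raises
    ------
    UnidentifiableRotationError
        If fewer than two pairs are given or the pairs are collinear.
    """
    v1 = np.atleast_2d(np.asarray(v1, dtype=float))
    v2 = np.atleast_2d(np.asarray(v2, dtype=float))
    if v1.shape != v2.shape or v1.shape[1] != 3 or v1.shape[0] < 2:
        raise UnidentifiableRotationError(
            f"need >= 2 paired 3-vectors, got shapes {v1.shape}, {v2.shape}"
        )
    C = v1.T @ v2  # maximize tr(R C)
    U, S, Vt = np.linalg.svd(C)
    scale = max(S[0], 1e-30)
    if S[1] / scale < 1e-9:
        raise UnidentifiableRotationError(
            "vector pairs are collinear: rotation about the common axis is free"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R


def hinge_angle_from_relative(R_rel: np.ndarray) -> float:
    """Hinge angle from a relative rotation: atan2(R[3,2], R[3,3]) (1-based).

    For R_rel = Rx(theta) this returns exactly theta in (-pi, pi]; it is the
    X-axis Euler angle of the relative orientation of the two segments.
    """
    R_rel = np.asarray(R_rel, dtype=float)
    if R_rel.shape != (3, 3):
        raise ValueError(f"expected 3x3 matrix, got shape {R_rel.shape}")
    return float(np.arctan2(R_rel[2, 1], R_rel[2, 2]))


def rotation_to_euler_zyx(R: np.ndarray) -> EulerZYX:
    """Decompose a body-to-world rotation into ZYX Euler angles."""
    R = np.asarray(R, dtype=float)
    pitch = float(-np.arcsin(np.clip(R[2, 0], -1.0, 1.0)))
    yaw = float(np.arctan2(R[1, 0], R[0, 0]))
    roll = float(np.arctan2(R[2, 1], R[2, 2]))
    return EulerZYX(yaw=yaw, pitch=pitch, roll=roll)


def euler_to_matrix(yaw, pitch, roll) -> np.ndarray:
    """Vectorized body-to-world matrices for arrays of ZYX Euler angles.

    Returns an (n, 3, 3) array (or (3, 3) for scalars).
    """
    yaw, pitch, roll = np.broadcast_arrays(
        np.asarray(yaw, float), np.asarray(pitch, float), np.asarray(roll, float)
    )
    ca, sa = np.cos(yaw), np.sin(yaw)
    cb, sb = np.cos(pitch), np.sin(pitch)
    cc, sc = np.cos(roll), np.sin(roll)
    R = np.empty(yaw.shape + (3, 3))
    R[..., 0, 0] = ca * cb
    R[..., 0, 1] = ca * sb * sc - sa * cc
    R[..., 0, 2] = ca * sb * cc + sa * sc
    R[..., 1, 0] = sa * cb
    R[..., 1, 1] = sa * sb * sc + ca * cc
    R[..., 1, 2] = sa * sb * cc - ca * sc
    R[..., 2, 0] = -sb
    R[..., 2, 1] = cb * sc
    R[..., 2, 2] = cb * cc
    return R
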