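"""Per-sensor attitude estimation.

Accelerometer roll/pitch, gyro dead-reckoning by explicit Euler integration of
the ZYX Euler-rate kinematics, complementary fusion of the two, stillness
detection by windowed acceleration variance, and reference-attitude averaging
over still periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rotations import (
    EulerZYX,
    SingularAttitudeError,
    UnobservableAttitudeError,
    accel_roll_pitch,
    body_rates_to_euler_rates,
)
from .sim import ImuSeries

log = logging.getLogger(__name__)


@dataclass
class AttitudeTrace:
    """Time-stamped ZYX Euler angles with a source tag (accel/gyro/fused)."""

    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    source: str = "fused"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.yaw = np.asarray(self.yaw, float)
        self.pitch = np.asarray(self.pitch, float)
        self.roll = np.asarray(self.roll, float)
        n = len(self.t)
        for name in ("yaw", "pitch", "roll"):
            a = getattr(self, name)
            if a.shape != (n,):
                raise ValueError(f"{name} length {a.shape} != t length {n}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite {name} values")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ComplementaryConfig:
    """Complementary-filter coefficient.

    ``alpha`` weights the (previous fused + gyro increment) term in the
    per-step recursive blend; the accelerometer term gets 1 - alpha.  The
    equivalent one-shot blend coefficient applied to the accel-gyro difference
    is K = 1 - alpha.
    """

    alpha: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def k(self) -> float:
        return 1.0 - self.alpha

    @classmethod
    def from_k(cls, k: float) -> "ComplementaryConfig":
        return cls(alpha=1.0 - k)


@dataclass(frozen=True)
class StillnessConfig:
    """Windowed accel-variance stillness test parameters."""

    window_s: float = 0.5
    threshold: float = 1e-3  # per-axis accel variance, (m/s^2)^2


def detect_still(series: ImuSeries, cfg: StillnessConfig | None = None):
    """Find still segments as maximal runs of low-variance accel windows.

    A window of ``cfg.window_s`` starting at sample i is still when the
    variance of every accel axis within it falls below ``cfg.threshold``.
    Returns a list of half-open sample intervals [start, end).
    """
    cfg = cfg or StillnessConfig()
    w = int(round(cfg.window_s * series.rate))
    if w < 2:
        raise ValueError(f"window {cfg.window_s}s is under 2 samples at {series.rate} Hz")
    n = len(series)
    if n < w:
        raise ValueError(f"series ({n} samples) shorter than window ({w})")
    a = series.accel
    c1 = np.vstack([np.zeros(3), np.cumsum(a, axis=0)])
    c2 = np.vstack([np.zeros(3), np.cumsum(a * a, axis=0)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    still_win = np.all(var < cfg.threshold, axis=1)  # length n - w + 1

    intervals = []
    i = 0
    m = len(still_win)
    while i < m:
        if still_win[i]:
            j = i
            while j + 1 < m and still_win[j + 1]:
                j += 1
            intervals.append((i, j + w))  # samples covered by still windows
            i = j + 1
        else:
            i += 1
    return intervals


def reference_attitude(series: ImuSeries, interval) -> EulerZYX:
    """Mean accelerometer roll/pitch over a still interval; yaw fixed at 0.

    Heading is unobservable from gravity alone, so yaw of the reference is 0
    by convention.  A non-still interval is accepted but logged as unreliable.
    """
    start, end = int(interval[0]), int(interval[1])
    if end <= start:
        raise ValueError(f"empty interval {interval}")
    seg = series.accel[start:end]
    if np.any(np.var(seg, axis=0) > 0.05):
        log.warning(
            "reference_attitude: interval [%d, %d) shows motion "
            "(accel variance %.3g); reference may be unreliable",
            start, end, float(np.max(np.var(seg, axis=0))),
        )
    angles = np.array([accel_roll_pitch(s) for s in seg])
    roll, pitch = angles.mean(axis=0)
    return EulerZYX(yaw=0.0, pitch=float(pitch), roll=float(roll))


def attitude_from_accel(series: ImuSeries, yaw: float = 0.0) -> AttitudeTrace:
    """Sample-wise accelerometer attitude (roll/pitch; yaw held constant).

    Samples with near-zero norm cannot define an attitude; they inherit the
    previous sample's angles and are counted in a warning.
    """
    n = len(series)
    roll = np.zeros(n)
    pitch = np.zeros(n)
    flagged = 0
    prev = (0.0, 0.0)
    for i, s in enumerate(series.accel):
        try:
            prev = accel_roll_pitch(s)
        except UnobservableAttitudeError:
            flagged += 1
        roll[i], pitch[i] = prev
    if flagged:
        log.warning("attitude_from_accel: %d near-zero samples carried forward", flagged)
    return AttitudeTrace(
        t=series.t, yaw=np.full(n, yaw), pitch=pitch, roll=roll, source="accel"
    )


def integrate_gyro(series: ImuSeries, initial: EulerZYX) -> AttitudeTrace:
    """Dead-reckon attitude by explicit Euler integration of the gyro.

    At each step the body rates are mapped to ZYX Euler-angle rates at the
    current attitude and advanced by dt.  First-order, matching the discrete
    update theta(t + dt) = theta(t) + omega dt; accuracy comes from sample rate.

    Raises
    ------
    SingularAttitudeError
        Naming the sample index if the trajectory approaches gimbal lock.
    """
    n = len(series)
    dt = series.dt
    out = np.zeros((n, 3))
    out[0] = initial.as_array()
    ang = initial.as_array().copy()
    for i in range(1, n):
        try:
            att = EulerZYX(yaw=ang[0], pitch=ang[1], roll=ang[2])
            rates = body_rates_to_euler_rates(att, series.gyro[i - 1])
        except SingularAttitudeError as exc:
            raise SingularAttitudeError(
                f"gimbal proximity at sample {i - 1} (t={series.t[i - 1]:.3f}s): {exc}"
            ) from exc
        ang = ang + rates * dt
        out[i] = ang
    return AttitudeTrace(
        t=series.t, yaw=out[:, 0], pitch=out[:, 1], roll=out[:, 2], source="gyro"
    )


def complementary_filter(
    accel_trace: AttitudeTrace,
    gyro_trace: AttitudeTrace,
    cfg: ComplementaryConfig | None = None,
) -> AttitudeTrace:
    """Recursive complementary fusion of accelerometer and gyro attitudes.

    Per step: fused = alpha * (previous fused + gyro increment)
                    + (1 - alpha) * accel.
    Yaw is always the gyro yaw — gravity carries no heading information.
    With alpha = 1 (K = 0) the output is the pure gyro trace; with alpha = 0
    (K = 1) it is the accelerometer trace (plus gyro yaw).
    """
    cfg = cfg or ComplementaryConfig()
    n = len(gyro_trace)
    if len(accel_trace) != n or not np.allclose(accel_trace.t, gyro_trace.t):
        raise ValueError("accel and gyro traces must share timestamps")
    a = cfg.alpha
    roll = np.zeros(n)
    pitch = np.zeros(n)
    roll[0] = a * gyro_trace.roll[0] + (1 - a) * accel_trace.roll[0]
    pitch[0] = a * gyro_trace.pitch[0] + (1 - a) * accel_trace.pitch[0]
    d_roll = np.diff(gyro_trace.roll)
    d_pitch = np.diff(gyro_trace.pitch)
    for i in range(1, n):
        roll[i] = a * (roll[i - 1] + d_roll[i - 1]) + (1 - a) * accel_trace.roll[i]
        pitch[i] = a * (pitch[i - 1] + d_pitch[i - 1]) + (1 - a) * accel_trace.pitch[i]
    return AttitudeTrace(
        t=gyro_trace.t, yaw=gyro_trace.yaw.copy(), pitch=pitch, roll=roll,
        source="fused",
    )


def estimate_attitude(
    series: ImuSeries,
    cfg: ComplementaryConfig | None = None,
    still_cfg: StillnessConfig | None = None,
) -> AttitudeTrace:
    """Full single-sensor pipeline: reference -> accel + gyro -> fused.

    The initial attitude is the averaged accelerometer attitude over the first
    detected still interval (or the first sample if no stillness is found).
    """
    intervals = detect_still(series, still_cfg)
    if intervals:
        init = reference_attitude(series, intervals[0])
    else:
        log.warning("estimate_attitude: no still interval; using first sample")
        r, p = accel_roll_pitch(series.accel[0])
        init = EulerZYX(yaw=0.0, pitch=p, roll=r)
    acc = attitude_from_accel(series)
    gyr = integrate_gyro(series, init)
    return complementary_filter(acc, gyr, cfg)
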