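"""CSV/JSON readers and writers for sensor streams and result traces.

On-disk conventions: SI units for sensor streams (m/s^2, rad/s, m, m/s) and
degrees for angle traces; one header row; columns matched by name so order is
free.  Timestamps must be uniform within 1e-6 s (resample upstream otherwise)
and gaps are rejected rather than silently interpolated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attitude import AttitudeTrace
from .joint import AngleTrace, JointCalibration
from .sim import GpsSeries, ImuSeries

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
GPS_COLUMNS = ["t", "px", "py", "pz", "vx", "vy", "vz"]
RAD2DEG = 180.0 / np.pi


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    bad = df[required].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise ValueError(f"{path}: missing/invalid value at row {row}, column {col!r}")
    return df


def _check_uniform(t: np.ndarray, path, tol: float = 1e-6) -> None:
    dt = np.diff(t)
    if len(dt) and np.max(np.abs(dt - dt[0])) > tol:
        k = int(np.argmax(np.abs(dt - dt[0])))
        raise ValueError(
            f"{path}: non-uniform timestamps near row {k + 1} "
            f"(dt {dt[k]:.6g} vs {dt[0]:.6g}); resample before loading"
        )


def read_imu_csv(path) -> ImuSeries:
    df = _read_table(path, IMU_COLUMNS)
    t = df["t"].to_numpy(float)
    _check_uniform(t, path)
    return ImuSeries(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
    )


def write_imu_csv(series: ImuSeries, path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.accel, series.gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def read_gps_csv(path) -> GpsSeries:
    df = _read_table(path, GPS_COLUMNS)
    return GpsSeries(
        t=df["t"].to_numpy(float),
        pos=df[["px", "py", "pz"]].to_numpy(float),
        vel=df[["vx", "vy", "vz"]].to_numpy(float),
    )


def write_gps_csv(series: GpsSeries, path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.pos, series.vel]), columns=GPS_COLUMNS
    )
    df.to_csv(path, index=False)


def write_attitude_csv(trace: AttitudeTrace, path) -> None:
    """Attitude trace on disk: degrees, columns t,yaw,pitch,roll,source."""
    df = pd.DataFrame(
        {
            "t": trace.t,
            "yaw": trace.yaw * RAD2DEG,
            "pitch": trace.pitch * RAD2DEG,
            "roll": trace.roll * RAD2DEG,
            "source": trace.source,
        }
    )
    df.to_csv(path, index=False)


def read_attitude_csv(path) -> AttitudeTrace:
    df = _read_table(path, ["t", "yaw", "pitch", "roll"])
    src = str(df["source"].iloc[0]) if "source" in df.columns else "fused"
    return AttitudeTrace(
        t=df["t"].to_numpy(float),
        yaw=df["yaw"].to_numpy(float) / RAD2DEG,
        pitch=df["pitch"].to_numpy(float) / RAD2DEG,
        roll=df["roll"].to_numpy(float) / RAD2DEG,
        source=src,
    )


def write_angle_csv(trace: AngleTrace, path) -> None:
    """Joint-angle trace on disk: degrees, columns t,angle,source."""
    pd.DataFrame(
        {"t": trace.t, "angle": trace.degrees(), "source": trace.source}
    ).to_csv(path, index=False)


def read_angle_csv(path) -> AngleTrace:
    df = _read_table(path, ["t", "angle"])
    src = str(df["source"].iloc[0]) if "source" in df.columns else "fused"
    return AngleTrace(
        t=df["t"].to_numpy(float),
        angle=df["angle"].to_numpy(float) / RAD2DEG,
        source=src,
    )


def write_calibration_json(calib: JointCalibration, path, extra: dict | None = None) -> None:
    from . import __version__

    payload = calib.to_dict()
    payload["tool_version"] = __version__
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration_json(path) -> JointCalibration:
    return JointCalibration.from_dict(json.loads(Path(path).read_text()))
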