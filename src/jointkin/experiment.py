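"""Error-injection study: how drift and soft-tissue artifacts corrupt
IMU joint-angle measurement, and how much each correction recovers.

Per seeded run the harness simulates the standard rig through a calibration
segment and a measurement segment, injects the condition's sensor errors,
self-calibrates on the (low-passed) calibration segment, and measures the
joint angle with four method variants:

* ``raw``          — integrated axial angular-rate difference only.
* ``gps``          — raw increments fused with low-rate absolute angle
                     observations derived from position fixes of the distal
                     sensor (a scalar Kalman filter bounds the drift).
* ``constraints``  — the full kinematic-constraint pipeline: wavelet
                     denoising, low-pass filtering, lever-arm-corrected
                     accelerometer angle, complementary fusion.
* ``combined``     — constraints pipeline plus the position-fix filter.

The per-run error metric is the mean absolute joint-angle error (MAE) against
simulator truth, with RMSE also recorded.  Groups are summarized as
mean ± sample SD with pooled two-sample t tests against the ``raw`` variant
(and, across conditions, against the control condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .joint import (
    AngleTrace,
    JointCalibration,
    build_joint_dataset,
    calibrate,
    joint_angle_gyro,
    joint_angle_pipeline,
)
from .kalman import KalmanState, LinearKalmanModel, kf_predict, kf_update
from .denoise import lowpass_imu
from .protocols import calibration_motion, measurement_motion, standard_rig
from .sim import (
    GpsSeries,
    SensorErrorModel,
    SyntheticDataset,
    corrupt,
    simulate_gps,
    simulate_hinge,
    with_seed,
)
from .stats import GroupStats, TTestResult, group_stats, two_sample_t

DEG = np.pi / 180.0
RAD2DEG = 180.0 / np.pi


@dataclass(frozen=True)
class Condition:
    """Per-sensor error models for one experimental condition."""

    name: str
    err1: SensorErrorModel
    err2: SensorErrorModel


def default_conditions() -> list[Condition]:
    """Control, sensor-drift, and soft-tissue-artifact conditions.

    Baseline sensor noise is shared; the drift condition adds opposite-sign
    constant gyro biases on the two sensors' axis components (equal biases
    would cancel in the rate difference), and the artifact condition adds a
    re-excited damped 5-degree mount oscillation on the distal sensor plus a
    milder bias pair.
    """
    base = dict(accel_noise_sd=0.02, gyro_noise_sd=0.003)
    return [
        Condition(
            "control",
            SensorErrorModel(**base),
            SensorErrorModel(**base),
        ),
        Condition(
            "drift",
            SensorErrorModel(**base, gyro_bias=(2.0 * DEG, 0.2 * DEG, -0.2 * DEG)),
            SensorErrorModel(**base, gyro_bias=(-1.0 * DEG, -0.2 * DEG, 0.2 * DEG)),
        ),
        Condition(
            "soft_tissue",
            SensorErrorModel(**base, gyro_bias=(0.5 * DEG, 0.1 * DEG, 0.0)),
            SensorErrorModel(
                **base,
                gyro_bias=(-0.5 * DEG, 0.0, -0.1 * DEG),
                st_amp_deg=5.0,
                st_freq_hz=8.0,
                st_damping=1.5,
                st_retrigger_s=2.0,
            ),
        ),
    ]


VARIANTS = ("raw", "gps", "constraints", "combined")


def angle_observations(
    fixes: GpsSeries, dataset: SyntheticDataset
) -> np.ndarray:
    """Project distal-sensor position fixes to absolute joint-angle observations.

    Valid for a stationary-base measurement segment: the distal sensor moves
    on a circle about the hinge axis, so the fix, projected onto the joint
    plane, reads the joint angle directly.  The rig geometry (axis and distal
    lever arm) comes from the simulator truth — an idealized absolute
    reference channel standing in for the paper-style position-fix correction.
    """
    axis = np.asarray(dataset.rig.axis, float)
    axis = axis / np.linalg.norm(axis)
    lever_w = np.asarray(dataset.rig.lever2, float)  # segment == world at theta=0
    u0 = lever_w - (lever_w @ axis) * axis
    u0 = u0 / np.linalg.norm(u0)
    v0 = np.cross(axis, u0)
    p_perp = fixes.pos - np.outer(fixes.pos @ axis, axis)
    return np.arctan2(p_perp @ v0, p_perp @ u0)


def anchor_with_fixes(
    trace: AngleTrace,
    fix_t: np.ndarray,
    fix_angle: np.ndarray,
    fix_sd: float,
    drift_sd_dps: float,
) -> AngleTrace:
    """Scalar Kalman filter fusing a trace's increments with absolute fixes.

    The state is the joint angle; prediction follows the input trace's
    per-sample increments with process noise sized for an assumed residual
    drift rate ``drift_sd_dps`` (deg/s); each fix epoch updates with variance
    ``fix_sd**2``.  Between fixes the filter predicts only, so the output
    follows the input trace's shape while its low-frequency error is pulled
    toward the absolute reference.
    """
    dt = float(trace.t[1] - trace.t[0])
    q = (drift_sd_dps * DEG) ** 2 * dt
    model = LinearKalmanModel(
        F=[[1.0]], H=[[1.0]], Q=[[q]], R=[[fix_sd**2]], B=[[1.0]]
    )
    idx = np.clip(np.round((fix_t - trace.t[0]) / dt).astype(int), 0, len(trace) - 1)
    fix_at = {int(k): float(a) for k, a in zip(idx, fix_angle)}
    inc = np.diff(trace.angle)
    state = KalmanState(x=[trace.angle[0]], P=[[fix_sd**2]])
    out = np.empty(len(trace))
    out[0] = state.x[0]
    if 0 in fix_at:
        state = kf_update(state, model, fix_at[0])
        out[0] = state.x[0]
    for k in range(1, len(trace)):
        state = kf_predict(state, model, u=inc[k - 1])
        if k in fix_at:
            state = kf_update(state, model, fix_at[k])
        out[k] = state.x[0]
    return AngleTrace(t=trace.t, angle=out, source=trace.source + "+fix")


@dataclass
class ExperimentConfig:
    """Study design knobs (durations in s; fix noise in m; rates in Hz)."""

    cal_duration: float = 12.0
    meas_duration: float = 60.0
    rate: float = 100.0
    fix_rate: float = 5.0
    fix_pos_sd: float = 0.02
    fusion_coefficient: float = 0.995
    lowpass_hz: float = 4.0
    gps_drift_sd_dps: float = 2.0       # assumed drift of the raw route
    combined_drift_sd_dps: float = 0.1  # assumed drift of the fused route


@dataclass
class ExperimentReport:
    """Aggregated error-injection study results."""

    seeds: list[int]
    config: ExperimentConfig
    mae: dict[str, dict[str, list[float]]]
    rmse: dict[str, dict[str, list[float]]]
    stats: dict[str, dict[str, GroupStats]] = field(default_factory=dict)
    ttests_vs_raw: dict[str, dict[str, TTestResult]] = field(default_factory=dict)
    ttests_vs_control: dict[str, TTestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seeds": self.seeds,
            "config": vars(self.config),
            "mae_deg": self.mae,
            "rmse_deg": self.rmse,
            "group_stats": {
                c: {v: vars(s) for v, s in d.items()} for c, d in self.stats.items()
            },
            "ttests_vs_raw": {
                c: {v: vars(t) for v, t in d.items()}
                for c, d in self.ttests_vs_raw.items()
            },
            "ttests_vs_control": {
                c: vars(t) for c, t in self.ttests_vs_control.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def render(self) -> str:
        lines = ["condition      " + "".join(f"{v:>16}" for v in VARIANTS)]
        for cond, d in self.stats.items():
            row = f"{cond:<15}"
            for v in VARIANTS:
                s = d[v]
                row += f"{s.mean:>8.2f}±{s.sd:<6.2f} "
            lines.append(row)
        lines.append("(joint-angle MAE vs truth, degrees, mean ± SD over seeds)")
        return "\n".join(lines)


def run_single(
    condition: Condition, seed: int, cfg: ExperimentConfig | None = None
) -> dict[str, AngleTrace | np.ndarray | float]:
    """One seeded run of one condition; returns traces, truth, and errors."""
    cfg = cfg or ExperimentConfig()
    rig = standard_rig(rate=cfg.rate)
    sim_cal = simulate_hinge(rig, calibration_motion(cfg.cal_duration))
    sim_meas = simulate_hinge(rig, measurement_motion(cfg.meas_duration))

    s = int(seed)
    cal1 = corrupt(sim_cal.imu1, with_seed(condition.err1, 7919 * s + 1))
    cal2 = corrupt(sim_cal.imu2, with_seed(condition.err2, 7919 * s + 2))
    m1 = corrupt(sim_meas.imu1, with_seed(condition.err1, 7919 * s + 3))
    m2 = corrupt(sim_meas.imu2, with_seed(condition.err2, 7919 * s + 4))

    # self-calibration on the low-passed calibration segment
    W_cal = build_joint_dataset(
        lowpass_imu(cal1, cfg.lowpass_hz), lowpass_imu(cal2, cfg.lowpass_hz)
    )
    calib = calibrate(W_cal)

    # absolute position fixes of the distal sensor, projected to joint angle
    fixes = simulate_gps(
        sim_meas.t, sim_meas.pos2, sim_meas.vel2,
        rate=cfg.fix_rate, pos_noise_sd=cfg.fix_pos_sd, vel_noise_sd=0.0,
        seed=7919 * s + 5,
    )
    obs = angle_observations(fixes, sim_meas)
    lever_w = np.asarray(rig.lever2, float)
    axis = np.asarray(rig.axis, float) / np.linalg.norm(rig.axis)
    r_perp = float(np.linalg.norm(lever_w - (lever_w @ axis) * axis))
    fix_sd = cfg.fix_pos_sd / r_perp

    W_meas = build_joint_dataset(m1, m2)
    raw = joint_angle_gyro(W_meas, calib.j1, calib.j2, alpha0=0.0)

    # resolve the calibration's arbitrary axis-sign convention against the
    # absolute reference once per run, uniformly for all variants
    at_fix = np.interp(fixes.t, raw.t, raw.angle)
    sgn = 1.0 if float(np.dot(at_fix - at_fix.mean(), obs - obs.mean())) >= 0 else -1.0
    raw = AngleTrace(t=raw.t, angle=sgn * raw.angle, source="gyro")

    pipe = joint_angle_pipeline(
        m1, m2, calibration=calib, coefficient=cfg.fusion_coefficient,
        lowpass_hz=cfg.lowpass_hz, denoise=True, alpha0=0.0,
    )
    constraints = AngleTrace(
        t=pipe["fused"].t, angle=sgn * pipe["fused"].angle, source="fused"
    )
    gps = anchor_with_fixes(raw, fixes.t, obs, fix_sd, cfg.gps_drift_sd_dps)
    combined = anchor_with_fixes(
        constraints, fixes.t, obs, fix_sd, cfg.combined_drift_sd_dps
    )

    truth = sim_meas.truth_angle
    out: dict = {"truth": truth, "calibration": calib}
    for name, tr in (("raw", raw), ("gps", gps),
                     ("constraints", constraints), ("combined", combined)):
        err = (tr.angle - truth) * RAD2DEG
        out[name] = tr
        out[f"mae_{name}"] = float(np.mean(np.abs(err)))
        out[f"rmse_{name}"] = float(np.sqrt(np.mean(err**2)))
    return out


def run_error_experiment(
    seeds=range(20),
    conditions: list[Condition] | None = None,
    cfg: ExperimentConfig | None = None,
) -> ExperimentReport:
    """Full study: every condition x variant x seed, with group statistics."""
    cfg = cfg or ExperimentConfig()
    conditions = conditions if conditions is not None else default_conditions()
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("need at least one seed")
    names = {c.name for c in conditions}
    if len(names) != len(conditions):
        raise ValueError("condition names must be unique")

    mae = {c.name: {v: [] for v in VARIANTS} for c in conditions}
    rmse = {c.name: {v: [] for v in VARIANTS} for c in conditions}
    for cond in conditions:
        for s in seeds:
            res = run_single(cond, s, cfg)
            for v in VARIANTS:
                mae[cond.name][v].append(res[f"mae_{v}"])
                rmse[cond.name][v].append(res[f"rmse_{v}"])

    report = ExperimentReport(seeds=seeds, config=cfg, mae=mae, rmse=rmse)
    if len(seeds) >= 2:
        for cond in conditions:
            report.stats[cond.name] = {
                v: group_stats(mae[cond.name][v]) for v in VARIANTS
            }
            report.ttests_vs_raw[cond.name] = {
                v: two_sample_t(mae[cond.name][v], mae[cond.name]["raw"])
                for v in VARIANTS if v != "raw"
            }
        if "control" in mae:
            for cond in conditions:
                if cond.name == "control":
                    continue
                report.ttests_vs_control[cond.name] = two_sample_t(
                    mae[cond.name]["raw"], mae["control"]["raw"]
                )
    return report
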