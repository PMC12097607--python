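# jointkin

Wearable-sensor joint kinematics for rehabilitation assessment: estimate a
hinge joint's angle and range of motion (ROM) from two body-worn inertial
measurement units (IMUs), with no manual sensor alignment or tape-measure
calibration.

After orthopedic surgery, ROM — the difference between the largest and
smallest joint angle a patient can reach — is a primary indicator of
recovery. Optical motion capture measures it accurately but needs a lab;
goniometers are cheap but manual and static. Two IMUs strapped to the
segments on either side of the joint can measure ROM continuously, if three
problems are solved: gyroscope integration drifts, accelerometers are noisy
and blind to heading, and nobody knows exactly how the sensors sit on the
limb. This package implements the full processing chain that addresses all
three, plus a rigid-body simulator that generates ground-truthed test data
for every stage.

## What is inside

| module | contents |
|---|---|
| `jointkin.rotations` | ZYX Euler-angle algebra: body-frame gravity, accelerometer roll/pitch, Euler-rate kinematics and its inverse, Wahba/Kabsch best-fit rotation, hinge-angle extraction |
| `jointkin.attitude` | stillness detection, reference attitude, gyro dead-reckoning, complementary filter |
| `jointkin.kalman` | linear Kalman predict/update, dead reckoning, per-axis [p, v, a] fusion of inertial data with position/velocity fixes |
| `jointkin.denoise` | multi-level wavelet decomposition, universal-threshold soft/hard shrinkage, zero-phase low-pass |
| `jointkin.joint` | kinematic-constraint self-calibration (joint axes and lever arms), four joint-angle estimators, ROM |
| `jointkin.sim` | analytic rigid-body simulator for two IMUs on a hinge limb; sensor error models; position-fix simulation |
| `jointkin.experiment` | seeded error-injection study (drift / soft-tissue artifact vs. correction method) with group statistics |
| `jointkin.io`, `jointkin.cli` | CSV/JSON I/O and the `jointkin` command-line tool |

## The core method

Sensor attitude uses intrinsic ZYX (yaw *a*, pitch *b*, roll *c*) Euler
angles. A static accelerometer reads gravity rotated into the sensor frame,
giving roll and pitch:

    roll = atan2(s_y, s_z),   pitch = −atan(s_x / √(s_y² + s_z²))

while the gyroscope propagates all three angles through the ZYX Euler-rate
kinematics. A complementary filter blends them per step,
`θ = α·(θ_prev + Δθ_gyro) + (1 − α)·θ_accel` (default α = 0.98), so gyro bias
cannot accumulate. Whole-body position drift is bounded the same way at a
larger scale: a per-axis [position, velocity, acceleration] Kalman filter
predicts with the (gravity-compensated) inertial acceleration and is
corrected by low-rate position/velocity fixes.

The joint-specific contribution is self-calibration from kinematic
constraints. If `g1`, `g2` are the angular rates of the two segments and
`j1`, `j2` the unit joint axis expressed in each sensor frame, a 1-DoF hinge
forces

    ‖g1 × j1‖ = ‖g2 × j2‖         (axis constraint)

at every instant, and with `Γ_g(o) = g × (g × o) + ġ × o` the acceleration
of the joint center seen from each sensor must agree:

    ‖a1 − Γ_g1(o1)‖ = ‖a2 − Γ_g2(o2)‖   (joint-center constraint)

Least-squares minimization of these residuals over arbitrary free movement
recovers the axes `j1, j2` and lever arms `o1, o2` — no measured mounting
geometry required. The joint angle then comes from integrating the axial
rate difference `g1·j1 − g2·j2` (drift-prone), from the angle between
joint-plane projections of the lever-corrected accelerations (noisy but
absolute), and from their complementary fusion; a fourth, independent route
aligns windowed gravity directions with an SVD (Kabsch) solution and reads
the hinge angle off the relative rotation matrix,
`θ = atan2(R_rel[3,2], R_rel[3,3])`.

Raw streams are wavelet-denoised before use: Daubechies-4, 5 levels, soft
thresholding at the universal threshold `λ = σ√(2 ln N)` with σ estimated
from the finest detail band.

## Worked example

`python examples/calibrate_and_measure_rom.py` self-calibrates from a 10 s
wobble-rich movement, then scores a stationary-base 0–60° flexion test:

```
estimated j1 = [-1.     0.001  0.   ]  (axis error 0.04 deg)
estimated levers: o1 = [ 0.004 -0.062  0.232] m, o2 = [-0.004 -0.138 -0.147] m
constraint residuals: axis 1.57e-03 rad/s, center 8.33e-03 m/s^2
fused joint-angle RMSE vs truth: 0.03 deg
range of motion: 60.1 deg (truth 60.0 deg)
```

The estimated axis is the hinge axis in the sensor frame (sign is a
convention; the flexion direction is fixed at calibration time), the lever
arms locate each sensor relative to the joint center up to the hinge's
axial gauge freedom, and the fused trace recovers the full 60° ROM within a
tenth of a degree under low sensor noise. The other examples cover attitude
fusion under gyro bias, wavelet denoising gain, position-fix drift
correction, and the error-injection study; each prints the numbers it
computes and a line about what they mean.

A thin CLI wraps the same calls:

```bash
jointkin simulate --amp 30 --freq 0.5 --duration 20 --noise-preset low --seed 1 --out data/
jointkin calibrate --imu1 data/imu1.csv --imu2 data/imu2.csv --out calib.json
jointkin angle --imu1 data/imu1.csv --imu2 data/imu2.csv --calib calib.json --out trace.csv
jointkin rom --trace trace.csv
```

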