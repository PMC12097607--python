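# Methods

This note documents the models implemented in `jointkin`, their assumptions,
the defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## Conventions

Attitude is intrinsic ZYX: yaw *a* about Z, pitch *b* about Y, roll *c* about
X, with the body-to-world rotation `R_wb = Rz(a) Ry(b) Rx(c)`. All internal
angles are radians; files and CLI output use degrees. Gravity is 9.81 m/s²
along −Z in the world frame, so a level, static accelerometer reads
`[0, 0, +g]`. The ZYX decomposition is singular at |pitch| = 90°; the
attitude type rejects it and the gyro integrator raises a sample-indexed
error within 10⁻³ rad of the singularity rather than propagating garbage.

## Attitude estimation

The accelerometer observes only the gravity direction: roll and pitch follow
from `roll = atan2(s_y, s_z)` and `pitch = −atan(s_x/√(s_y²+s_z²))`; atan2
preserves the roll quadrant while the pitch denominator is nonnegative, so
pitch stays in (−90°, 90°). Heading is unobservable from gravity and is set
to 0 at the reference; all fused traces carry the gyro yaw.

Gyro dead reckoning uses explicit (first-order) Euler integration of the ZYX
Euler-rate kinematics. The forward map (Euler rates → body rates) is

    ω = Rx(−c)Ry(−b)[0,0,ȧ]ᵀ + Rx(−c)[0,ḃ,0]ᵀ + [ċ,0,0]ᵀ

and the inverse is its exact algebraic inverse; both are verified against
each other by round trip to 10⁻¹⁰ and against finite differences of smooth
trajectories. First-order integration was chosen over a quaternion
integrator for transparency; its error is O(A·ω·Δt) and stays below 0.1° at
100 Hz for moderate motion (15° amplitude at 0.25 Hz). Faster motion or
lower rates inflate this term — the convergence test halves Δt and checks
the endpoint shift.

The complementary filter is the per-step recursion
`θ_k = α(θ_{k−1} + Δθ_gyro) + (1−α)θ_accel` with α = 0.98 at 100 Hz
(crossover time constant αΔt/(1−α) ≈ 0.5 s). The equivalent blend
coefficient applied to the accel−gyro difference is K = 1−α;
`ComplementaryConfig.from_k` exposes that convention. Under a constant gyro
bias β the fused angle converges to a steady offset ≈ β·αΔt/(1−α) instead of
a linear drift — the property the bias tests assert.

Stillness is detected by windowed per-axis accelerometer variance (window
0.5 s, threshold 10⁻³ (m/s²)² per axis by default); reference attitude is
the mean accelerometer attitude over a still interval. Joint-level anchoring
uses the first interval during which *both* sensors are still, because a
stationary proximal segment is "still" even while the joint flexes.

## Trajectory fusion with position fixes

The filter is the textbook linear Kalman recursion; the covariance update is
evaluated in the Joseph-stabilized form `(I−KH)P(I−KH)ᵀ + KRKᵀ`, which is
algebraically identical to `(I−KH)P` for the optimal gain but preserves
symmetry and positive semidefiniteness in floating point (the PSD invariant
is exercised over 10⁵ randomized steps).

Per world axis the state is [position, velocity, acceleration] with the
bidiagonal constant-acceleration transition (rows `[1, Δt, 0; 0, 1, Δt;
0, 0, 1]`) by default; `half_dt2=True` switches to the full transition with
the ½Δt² position term, which is what the noise-free 10⁻³ m tracking test
uses (the bidiagonal chain has a first-order model error of a few mm at
100 Hz). Process noise is the standard discrete white-noise-jerk matrix with
spectral density q = 0.1 (m/s²)²/s.

The world-frame inertial acceleration (attitude-rotated, gravity-subtracted)
enters as a high-rate measurement of the acceleration state with variance
`r_acc = 0.25` (m/s²)². This default is deliberately far above the
accelerometer noise floor: accelerometer bias is slowly varying rather than
white, and a filter that trusts the accelerometer at its noise level tracks
the bias into a steady-state position lag of meters. Inflating `r_acc` is
the standard robustness remedy short of augmenting the state with a bias
term (out of scope). Fixes update position and velocity at their epochs
(nearest IMU sample, no interpolation) with `r_pos = 1 m²`,
`r_vel = 0.01 (m/s)²`; between epochs the filter predicts only, which is the
dead-reckoning regime whose quadratic drift (½εT², 360 m for ε = 0.05 m/s²
over 120 s) the fixes bound to well under 2 m RMS.

## Wavelet denoising

Defaults: Daubechies-4, 5 decomposition levels, symmetric boundary, soft
thresholding at the universal threshold λ = σ√(2 ln N), σ estimated as
MAD/0.6745 of the finest detail band (a fractional-of-signal-sd override is
available). Signals of awkward length are handled by the transform's
boundary padding and trimmed to the input length after reconstruction. Only
soft and hard rules are provided; no "improved" threshold function is
implemented because no formula defines one.

The denoising benchmark is a 1 Hz unit sinusoid sampled at 200 Hz for 10 s
with Gaussian noise at 10 dB SNR. The sampling rate matters: at 5 levels the
approximation band ends at fs/64, and the wavelet filters are not brick
walls, so a signal too close to that edge leaks into the finest kept detail
band and is attenuated by the threshold. At 200 Hz the 1 Hz tone sits deep
in the approximation band and the pipeline delivers ≈ 14 dB of SNR gain.
Zero-phase Butterworth low-pass filtering (default cutoff 4 Hz, order 4) is
a separate utility used by the joint pipeline: joint motion lives below a
few Hz while soft-tissue oscillation sits near 8 Hz, and thresholding alone
does not remove an artifact whose coefficients are large.

## Hinge self-calibration

For a 1-DoF hinge the two segments' angular velocities differ only by the
hinge rate about the joint axis, so the projections onto the joint plane
have equal norms: the axis residual is `‖g1×j1‖ − ‖g2×j2‖`. Axes are
parametrized on the sphere (azimuth, elevation) and fitted by
Levenberg–Marquardt from eight deterministic starts (unit cube corners);
gradient tolerance 10⁻¹⁰, at most 1000 residual evaluations per start.

The constraint is even in each axis, so two sign conventions are fixed
deterministically after the fit: the *pair* consistency (j2 flipped so that
rotating it into sensor-1 coordinates via the Kabsch-estimated relative
orientation of paired gravity directions aligns it with j1 — this projection
is invariant to the hinge angle), and the *flexion direction* (overall pair
sign chosen by the majority sign of the axial rate difference at its largest
excursions). The flexion direction is genuinely unobservable without
anatomical information; estimated traces are therefore compared to ground
truth up to a global sign, and the experiment harness resolves the sign once
per run against its absolute reference channel.

The joint-center residual is `‖a1 − Γ_g1(o1)‖ − ‖a2 − Γ_g2(o2)‖` with
Γ_g(o) = g×(g×o) + ġ×o, the unique rigid-body acceleration of a point at
lever arm o. Angular accelerations come from differentiating the gyro: a
five-point (fourth-order) central stencil in the interior, one-sided at the
ends. The second-order three-point stencil proved insufficient here — its
O(Δt²) truncation bias, though only ~10⁻⁴ rad/s², is correlated and biased
the shallow center cost by ~7 mm at 100 Hz. Optimization runs from the
origin plus six ±5 cm axis-aligned starts.

For a hinge every point on the axis is a joint center, so (o1, o2) is
identifiable only up to a common shift along (j1, j2). The estimator returns
the canonical gauge representative with `o1·j1 + o2·j2 = 0`, and accuracy is
measured gauge-invariantly (truth mapped to the same representative).

Identifiability requires genuine excitation. The estimators refuse records
whose RMS angular rate (axes) or RMS angular acceleration (centers) is below
0.05 in SI units. Two subtler degeneracies shaped the standard calibration
protocol: a proximal segment that rotates about a *single fixed axis* leaves
its joint axis on an unidentifiable cone and its lever arm free along one
direction, and base rotation *perpendicular* to the hinge axis makes the
axis cost only second-order sensitive for that sensor. The calibration
movement therefore combines flexion (25° amplitude, 0.5 Hz about a 30° mean)
with a two-component whole-limb wobble (15° at 0.4 Hz and 12° at 0.6 Hz)
about axes tilted toward the hinge axis. This is the "move the limb freely"
instruction made concrete.

## Joint-angle estimation

Four routes, sharing the calibrated geometry:

* **Gyro** — trapezoidal integration of `g1·j1 − g2·j2`. Exact for constant
  rates; drifts at exactly the axial component of any single-sensor gyro
  bias, while a bias common to both axial projections cancels.
* **Accelerometer** — both accelerations are shifted to the joint center
  (`a − Γ_g(o)`), projected onto each sensor's joint plane, and converted to
  in-plane phases; the phase difference (φ2 − φ1, whose sign convention
  matches the gyro route) tracks the joint angle absolutely but noisily. The
  trace is anchored to a known angle over the first joint-still interval.
  Samples whose projection is nearly axis-parallel (< 1 m/s²) are flagged
  and carried forward.
* **Fused** — the same complementary recursion as the attitude filter
  (default coefficient 0.98): gyro increments high-pass, accelerometer angle
  low-pass.
* **SVD** — within a sliding window (default 1 s) the unit
  (lever-corrected) acceleration vectors of the two sensors are paired
  observations of common world directions; the Kabsch best-fit rotation
  mapping sensor-2 pairs onto sensor-1 is the relative orientation, and the
  hinge angle is `atan2(R_rel[3,2], R_rel[3,3])`, anchored at the first
  valid window. The model assumes the joint angle is quasi-static within a
  window; windows without directional variety (e.g., everything still, or a
  stationary base with no wobble) are degenerate and carried forward, and
  windows containing fast flexion are biased. Validation therefore uses a
  hold-and-move protocol (stepwise flexion with continuous small wobble) and
  asserts exactness (< 0.1°) on samples whose entire window is inside a
  hold, plus < 1° agreement with the fused route there.

The measurement pipeline wavelet-denoises, low-passes at 4 Hz, builds the
dataset, applies a supplied calibration (or self-calibrates), and runs the
three non-SVD routes. ROM is the min/max/range of the chosen trace in
degrees.

## The simulator

Two segments share a hinge at the origin; the proximal segment optionally
rotates through a composition of fixed-axis wobbles, the distal one adds the
hinge rotation. Angular velocity, angular acceleration, and the sensor-point
acceleration (gravity plus centripetal and tangential lever terms) are all
evaluated analytically from the motion profiles — no internal numerical
differentiation — so the streams are oracle-grade: the axial-rate identity
and the Γ-consistency of the accelerometer model hold to 10⁻⁸ or better,
and the truth angle trace matches the hinge angle recovered from the truth
relative attitudes to 10⁻¹⁰. Truth axes are oriented so that
`g1·j1 − g2·j2 = +dθ/dt`.

Profiles: sinusoid `mean − A·cos(2πft)` (range exactly 2A, zero rate at
whole-period boundaries, so still padding joins with continuous velocity),
linear ramp, and a hold-and-move step schedule with cosine transitions.
Defaults are a knee-like rig: mediolateral axis, mounts rotated ±(20°, 35°)
about it, levers (0.03, 0.02, 0.24) m and (0.02, −0.03, −0.20) m, 100 Hz
sampling, 1 Hz position fixes.

The error model adds, in order: soft-tissue artifact (a damped oscillation
of the mount orientation, default 8 Hz, damping per preset, optionally
re-excited every couple of seconds the way skin wobble is re-excited by
movement reversals — both the rotated signals and the oscillation's own
angular rate are applied), constant biases, a gyro bias random walk, and
white Gaussian noise, all reproducible from a seed. What the simulator does
*not* model: inter-sensor clock skew, accelerometer scale/cross-coupling
errors, magnetic disturbance (no magnetometer anywhere), non-hinge joint
laxity, and soft-tissue *translation*. Passing the synthetic suite therefore
demonstrates correctness of the algorithms under the stated error models,
not clinical accuracy on human data.

## The error-injection study

Three conditions (control; sensor drift = ±(2, −1)°/s axial gyro biases on
the two sensors; soft-tissue = 5° re-excited 8 Hz mount oscillation on the
distal sensor plus mild ±0.5°/s biases) are crossed with four estimators
(raw gyro integral; raw + position-fix filter; constraint pipeline with
fusion coefficient 0.995; constraint pipeline + position-fix filter) over
seeded runs of a 10 s calibration segment and a 60 s measurement segment.
The per-run metric is the joint-angle MAE in degrees against simulator
truth (RMSE is recorded alongside); groups are reported as mean ± sample SD
with pooled two-sample t tests (Welch available behind a flag), and table
output rounds half-up to one decimal while the JSON keeps full precision.

The "position fix" channel deserves a caveat: real satellite positioning
(σ ≈ 1 m) cannot observe a joint angle through a ~0.2 m lever arm. The
harness instead simulates precise fixes (2 cm, 5 Hz) of the distal sensor
and projects them through the true rig geometry into coarse absolute angle
observations (σ ≈ 6°), fused with each trace's increments by a scalar Kalman
filter. This keeps the mechanism under study — absolute references bound
integration drift — while being explicit that at limb scale the reference
would in practice be a UWB/RTK-grade or camera-based fix. The assumed
residual drift rates of the anchor filter are 2°/s for the raw route and
0.1°/s for the fused route, matching their actual drift behavior. Injected
error magnitudes are the package's own study design (chosen once, before
freezing the ordering checks); only the qualitative structure — raw worse
than its matching correction, combined best — is asserted, in ≥ 95% of 20
seeded runs.

## Numerical details and degenerate inputs

* Kabsch uses the SVD determinant correction `diag(1, 1, sign det)`; pair
  sets whose second singular value is below 10⁻⁹ of the first are rejected
  as collinear.
* Wavelet thresholding at λ = 0 is the identity by construction (the
  library's soft rule would evaluate 0/0 on exactly-zero coefficients).
* CSV readers reject non-uniform timestamps (tolerance 10⁻⁶ s) and missing
  values with row/column diagnostics instead of interpolating.
* The t test returns t = 0, p = 1 for identical zero-variance groups and
  raises for zero variance with unequal means.
* Angle-trace problems (flagged SVD windows, axis-parallel accelerations)
  carry the last valid value forward and log a count, rather than failing a
  whole record for transient degeneracy.

## Known limitations

Single-DoF joints only; no magnetometer, so heading is relative; explicit
Euler attitude integration limits very fast motion at low sample rates; the
accelerometer joint-angle route assumes the joint center's own acceleration
is shared (exact here, approximate if the joint translates); the SVD route
requires attitude variety and quasi-static windows; and all accuracy claims
are with respect to the simulator's error models, not human recordings.
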