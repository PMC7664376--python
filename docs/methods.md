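# Methods

This note documents the models implemented in `headpdr`, the conventions
and defaults they use, what the synthetic walking simulator does and
does not emulate, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

An `ImuSequence` carries time-stamped tri-axial accelerometer (m/s²,
specific force), gyroscope (rad/s) and optional magnetometer (unit-free
direction) samples, nominally at 20 Hz. Timestamps are validated to be
strictly increasing and the median interval must lie within 20% of the
nominal rate; all filtering and integration uses per-sample Δt rather
than assuming uniform sampling, because Bluetooth logging jitters. Gyro
columns logged in deg/s are converted to rad/s at load.

Frames: world x/y horizontal, z up. Quaternions are scalar-first unit
quaternions q = (q0,q1,q2,q3) representing the body-to-world rotation;
Euler angles are intrinsic Z-Y-X with pitch in [−π/2, π/2]. Estimator
yaw ψ is counter-clockwise about z starting from 0 (there is no absolute
north reference without a magnetometer, so trajectories live in a
walk-relative frame whose initial walking direction is +x). Step
headings for the position update are measured from +y, φ = π/2 − ψ, so
the update reads x += l·sinφ, y += l·cosφ. Yaw series are accumulated
unwrapped so step integration never sees a 2π jump.

## Step detection

The filter is the simplest causal first-order low-pass: exponential
smoothing y[n] = α·x[n] + (1−α)·y[n−1] with α = Δt/(RC+Δt),
RC = 1/(2π f_c), initialised at the first sample; DC gain is exactly 1.
The cut-off default is 2 Hz — above any normal step frequency, below
most sensor noise. A causal (not zero-phase) realisation was chosen
because the method should remain usable online; the constant group
delay shifts detected peaks by a sample or two but cancels out of all
per-step quantities.

Peaks of the filtered norm above a threshold are steps. Defaults:
threshold g + 0.5 = 10.31 m/s² (the filtered norm oscillates about
gravity during level walking; the threshold is applied to the raw
filtered norm, not a gravity-subtracted one) and a 0.3 s minimum
peak-to-peak separation (maximum credible cadence ≈ 3.3 steps/s).
Suppression is best-first: higher peaks win, earlier index breaks ties,
and the first sample of a plateau is the peak — all deterministic. The
5 s standstills produce no peaks by construction (norm ≈ g below
threshold), so no trimming is needed.

Step windows are assigned midway between adjacent peaks, the first
starting at sample 0 and the last ending at the end of the stream, so
windows tile the walk without overlap. Inside the pipelines each window
is additionally clamped to one median inter-peak period centred on its
peak (`PipelineConfig.max_window_factor = 1.0`): without the clamp the
first and last windows swallow the standstill periods, yielding
nonsense per-step frequencies (≈0.1 Hz for a 5 s window) that corrupt
duration-based length models and can produce misleading endpoint
artifacts. A step spans one gait period; the clamp encodes exactly that.

## Step-length models

Per-step features from the filtered norm within the window: step
frequency f = fs/N, extrema a_max/a_min, mean absolute value, and the
population variance v (divide by N — a per-step descriptive statistic).
The filtered norm is used rather than a gravity-projected vertical
component: a head-mounted sensor is near-level, and the norm is what the
detection stage already computes; treating the norm as the "vertical
acceleration" of the amplitude models is an approximation noted under
limitations. The variance fed to the hybrid model is likewise the
variance of the norm.

All six models are linear in their free coefficients, so calibration is
ordinary least squares against known step lengths (path length divided
by step count on a measured walk). For the hybrid model the correlation
weights r_lf and r_lv are computed first as sample Pearson coefficients
of length against frequency and against variance over the calibration
set, then (a, b) are fitted with the variance coefficient pinned at
r_lv. Note the hybrid therefore needs cadence variation in its
calibration data — with constant-cadence steps the correlations are
undefined — which is why the calibration helpers use several short
walks at different cadences. Calibration rejects rank-deficient designs
and fewer observations than free parameters. `collect_calibration_steps`
drops one step at each end of a calibration walk by default, where
windows abut the standstills.

The shipped demo default Weinberg gain is k = 0.48, but per-subject
calibration is always preferred; borrowed population coefficients are
precisely what makes the linear-model comparator inaccurate. The
comparator configuration ships with linear coefficients a = 0.30,
b = 0.10 m deliberately *not* calibrated to the simulator's gait, to
represent that method's historical use of population-level values.

## Heading estimators

**Mahony explicit complementary filter** (the proposed method's
estimator). Per sample: v = a/|a| is the measured gravity direction,
v̂ = R(q)ᵀ(0,0,1)ᵀ the estimated one, e = v × v̂ the correction;
the quaternion rate is q̇ = ½ q ⊗ p(Ω + k_P·e + k_I·Σe·Δt), integrated
with one explicit Euler step and renormalised (unit norm is preserved to
1e−9 per step indefinitely). The integral accumulator is Δt-scaled so
behaviour is sample-rate independent; the accumulated term k_I·Σe·Δt is
algebraically the negative of a gyro-bias estimate, exposed as
`bias_hat`, and on static data it converges to the true bias in the two
axes observable from gravity (the component along gravity is
unobservable without a magnetometer — yaw drift from z-axis gyro bias is
the method's irreducible error). A zero-norm accelerometer sample skips
the correction (pure gyro propagation). Defaults k_P = 1.0, k_I = 0.1
give a ~1 s attitude-error time constant and stable bias convergence on
the simulator; both are exposed in configuration, as such gains are in
practice tuned per platform. Initial attitude comes from the mean
accelerometer vector over the first 2 s of standstill (the collection
protocol guarantees 5 s), with initial yaw defined as 0.

**Hybrid gyro/magnetometer azimuth** (comparator). φ_gyr integrates the
body z-rate only on samples whose gyro norm exceeds a threshold
(default 0.05 rad/s); φ_mag is the tilt-compensated magnetic azimuth
(roll/pitch from the per-sample accelerometer, magnetometer de-rotated
to the horizontal plane), referenced to its initial value so both terms
share the walk-relative origin. Output is k_gyr·φ_gyr + k_mag·φ_mag with
defaults 0.9/0.1 — the gains are set manually in the original method and
no published values exist.

**Euler-angle EKF** (comparator). State x = [roll, pitch, yaw, ωx, ωy,
ωz]; process model: Euler-rate kinematics θ̇ = E(θ)ω with constant-rate
assumption ω̇ = 0, discretised per sample; measurement model: the gyro
observes ω directly and the accelerometer observes R(θ)ᵀ(0,0,g)ᵀ. Both
Jacobians are analytic and verified against central finite differences
in the tests. The covariance is re-symmetrised after every update.
Default noise matrices are diagonal and sized from the low-cost sensor
noise levels (gyro σ = 0.01 rad/s, accel σ = 0.2 m/s²); Q defaults to
1e−6 on angles and 2.5e−3 on rates per step. The source method
publishes only its state and measurement vectors, so this process model
and these Jacobians are one consistent reconstruction. Note the EKF
carries no gyro-bias state: its yaw column in the measurement Jacobian
is identically zero, which makes its yaw a near-optimally smoothed gyro
integral under white noise, but leaves nothing to cancel rate bias —
the integral term of the complementary filter is the proposed method's
structural advantage on uncalibrated gyros.

## Trajectory assembly and metrics

Each pipeline: detect steps on the filtered norm, extract per-step
features, predict lengths with its model, estimate the yaw series with
its estimator, sample yaw at each step's peak instant (a window-averaged
variant can be configured), map to step headings, and chain the step
vectors. Estimated trajectory length is the polyline length, which
equals the sum of step lengths exactly. End-to-end error is measured to
the trajectory's own start (it coincides with the ground-truth start for
the closed benchmark path). Negative model predictions are clipped to
zero length.

## The synthetic walking simulator

The simulator emulates the standard collection protocol for this kind of
study: stand still 5 s, walk a waypoint path at constant cadence with
the head facing the walking direction, stand still 5 s; the default
benchmark path is a 25.5 m × 8.5 m rectangle (68 m perimeter) at 20 Hz.
Ground truth is constructed at the step level — n = round(edge/step
length) steps per edge, heading ramped through corners at a bounded
turn rate (default 45°/s) — and the ground-truth trajectory is exactly
the chained step vectors, so its length is exactly step_length × steps.

The continuous signals are built to be exactly consistent with that
ground truth: yaw is piecewise-linear through mid-step knots; the head
additionally pitches sinusoidally at the step frequency (default 3°),
since a gait-silent gyroscope on straight segments would match no real
head-mounted recording and would make threshold-gated integration
artificially clean; gyro samples are the exact discrete rates carrying
the attitude from each sample to the next, so an independent quaternion
integration of the noise-free gyro reproduces the ground-truth yaw. The
world-frame specific force is gravity plus one vertical sinusoidal peak
per step (default amplitude 2 m/s²) and a quadrature fore-aft component
along the walking direction (default 1.5 m/s²) — heads accelerate and
brake once per step. With the fore-aft amplitude below ~2 m/s² the
accelerometer-norm extrema remain exactly g ± the vertical amplitude and
the norm has exactly one peak per step, preserving the step-detection
ground truth by construction.

Sensor errors are i.i.d. Gaussian per axis plus a constant per-trial
gyro bias and a horizontal magnetic field at a fixed declination;
identical seeds give bit-identical output. Defaults model a low-cost
MEMS module after routine boot calibration: accel σ = 0.2 m/s², gyro
σ = 0.01 rad/s, gyro bias (0.002, −0.002, 0.001) rad/s, magnetometer
direction noise at 15% of the field.

What the simulator does **not** emulate — and therefore what passing
tests do and do not show: no lateral sway or independent head-gaze
motion; no horizontal acceleration transients at gait initiation or
termination; no spatially-varying magnetic disturbances (white noise
plus fixed declination only — real buildings are far harsher on
magnetometer headings, so the hybrid comparator's simulated accuracy is
an upper bound on its real behaviour); no soft-tissue artefact; no
step-length variability within a walk; perfectly constant cadence.
Results on simulated walks demonstrate internal consistency and the
relative structural strengths of the methods, not field accuracy.

## Numerical choices and degenerate inputs

Quaternion normalisation after every filter step; the asin argument in
the Euler conversion is clamped to [−1, 1]; Euler round-trips are exact
to 1e−9 away from gimbal lock (|pitch| ≤ 85°). Plateau peaks take their
first sample; peak suppression is best-first with index tie-break.
Weinberg returns 0 with a logged warning when a step has zero
acceleration range; Scarlett raises on the same degenerate input, since
its ratio is undefined. Pearson correlation raises on zero variance.
The EKF raises on non-positive-definite Q or R and re-symmetrises P
each step. Empty detection output is valid and yields a zero-length
trajectory.

## Known limitations

* Yaw is unobservable from gravity: z-axis gyro bias integrates into
  heading drift for every magnetometer-free method here, including the
  proposed one. On the simulator this drift is the dominant error term.
* Under purely white sensor noise a correctly-specified EKF is close to
  statistically optimal, so the proposed method's advantage on the
  simulator rests on the comparators' genuine structural weaknesses
  (borrowed step-length coefficients; noise-sensitive variance term in
  the hybrid length model), not on a large heading gap; real-data
  effects (magnetic disturbance, unmodelled dynamics, tuning drift
  across placements) are expected to widen the gap but are not
  simulated.
* The amplitude step-length models use the accelerometer norm as a
  stand-in for vertical acceleration; on strongly tilted mounts a
  gravity projection would be preferable.
* Level walking only: no stairs, no altitude, no map constraints.
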