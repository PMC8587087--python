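# Methods

This note documents the models and numerical choices behind `gaitspan`:
the sensor algorithm, the gait-laboratory reference, the synthetic
treadmill world used for validation, and the known limits of each.

## Conventions

Internal units are SI throughout (s, m, m/s², rad/s); readers normalize
declared input units (deg/s, g) on load, so normalization is idempotent.
Time is seconds from trial start; all event windows are half-open
`[start, end)`.  World frame: x anterior–posterior, y lateral, z up.
Sensor frame (lateral shank mount): x along the shank, y
anterior–posterior, z perpendicular to the sagittal plane.  A
right-handed frame cannot put x up the shank, y forward *and* z
lateral-outward on both legs, so mirrored mounts imply one sensor is worn
inverted; nothing in the pipeline needs to know which — the mid-swing
sign is normalized from the data (the sign with the larger 99th
percentile of |ωz| wins) and the lever-arm direction is recovered from
the orientation estimate.  Left and right are processed independently and
never averaged, so asymmetric deficits are preserved.

## Event detection

All detection thresholds adapt to the individual recording; nothing is
tuned to a walking speed.

* **Cycle duration.**  `T_cycle = 1/f_max`, with `f_max` the *first main*
  component of the magnitude spectrum of mean-removed ωz — the
  lowest-frequency in-band (0.2–2.0 Hz, i.e. strides of 0.5–5 s) spectral
  peak reaching at least 50% of the in-band maximum.  A single shank's
  ωz is a once-per-cycle pulse train whose second harmonic can rival the
  fundamental (at faster cadences it exceeds it); taking the raw spectral
  argmax would then halve `T_cycle` and shrink every adaptive window, so
  the first-main-peak rule is essential, not cosmetic.  The FFT is
  zero-padded to a ≤0.01 Hz grid; signals shorter than ~10 s or without
  any in-band component above the numerical floor raise an error.
* **Mid-swing.** ωz peaks with height ≥ `0.20 ×` (99th percentile of ωz)
  and spacing ≥ `0.5 · T_cycle`; greedy suppression keeps the higher
  peak, ties break toward the earlier sample.  Percentiles use linear
  interpolation.  Because both thresholds are relative, scaling the
  signals by any positive constant moves no event (property-tested).
* **IC/FC/MST.**  Implemented exactly as windowed extrema anchored on MSW
  (5–45% after for IC, −35–−5% before for FC, the stance interval for
  MST), using the trial-level `T_cycle`, global window extrema for FC,
  and sample-resolution event times (errors of interest are already at
  the 5 ms resolution of 200 Hz sampling; the FC midpoint may fall on a
  half-sample).  An IC window without an interior local maximum falls
  back to the window maximum and flags the stride.  Boundary cycles whose
  windows leave the recording are dropped and counted in the log.

## Trajectory reconstruction

* **Orientation.**  Complementary filter: per-sample gyroscope strapdown
  (quaternion exponential), tilt corrected toward the
  accelerometer-implied vertical with gain 0.01 per sample at 200 Hz.
  The correction weight falls linearly to zero as the specific-force
  magnitude departs from gravity by up to 0.2 m/s², and the departure is
  evaluated as a running maximum over ±50 ms.  Both choices matter: an
  instantaneous `|a| = g` crossing mid-swing has a badly wrong direction,
  and admitting such samples biases stride length by tens of millimetres
  at slow speeds.  With sustained gating, corrections effectively happen
  in the quasi-static mid-stance window once per stride, which is enough
  to bound tilt drift.  Yaw is unobservable without a magnetometer and is
  left free; heading alignment fixes it per stride.  The initial tilt
  comes from the mean accelerometer vector over the first 0.5 s; if that
  vector is >2 m/s² away from gravity the filter warns and starts from
  identity.
* **Gyroscope bias** is estimated from still spans before integration: a
  0.5 s window counts as still only if every axis has SD < 0.03 rad/s
  *and* the mean rate is < 0.1 rad/s.  The rate condition excludes the
  quiet mid-stance plateau of slow gait, which is low-variance but
  genuinely rotating at 0.2–0.3 rad/s and otherwise poisons the estimate.
  Without a still span (no standing in the recording) the bias is left in;
  the linear drift correction then absorbs most of its first-order effect.
* **Integration.**  Each MST→MST segment of world acceleration
  (`R(q)·a − g ẑ`) is integrated twice with the trapezoidal rule.  The
  raw velocity is corrected by subtracting a linear-in-time term so it
  equals the boundary estimates at both anchors — the minimal correction
  consistent with the first-order drift that white accelerometer noise
  and a residual constant acceleration error produce.  Constant
  acceleration errors cancel exactly under this correction; only their
  within-stride curvature survives.
* **Boundary velocities.**  `|v| = |ω| · r` with `r = 0.10 m` by default.
  The vector form used internally is `R(ω × r x̂)`: the sensor pivots
  about the planted ankle, so its velocity is the angular rate crossed
  with the lever arm, directed along the shank's forward tangent.  On a
  treadmill this estimate deliberately ignores the belt: the stance foot
  moves with the belt, but `ω·r` is its speed *relative to the belt*, so
  the reconstructed trajectory lives in the belt frame and the forward
  displacement directly measures stride length — the same reason the
  estimate is exact for overground walking.
* **Long strides.**  Segments > 2.5 s are first high-pass filtered
  (first-order Butterworth, 0.0002 Hz, zero-phase).  At that cutoff the
  filter's time constant (~800 s) dwarfs a stride, so on a per-stride
  segment it is a near no-op *when applied correctly*: `filtfilt`'s
  default reflect-padding initializes it to steady state, which would
  subtract the entire segment mean (≈150 mm stride-length error at
  0.3 m/s); the Gustafsson edge method is used instead.  Drift control
  for slow strides therefore rests on the boundary correction.
* **Heading and spatial parameters.**  Each stride is rotated about z so
  the mean horizontal swing velocity points along +x (flagged and left
  unrotated below 1 mm/s).  Stride length is max forward displacement
  from the segment start; width and height are lateral and vertical
  ranges.  MST→MST segments are mapped to strides by which IC falls
  inside the segment — the same rule is applied to the synthetic truth,
  so comparisons are segment-consistent.

## Gait-laboratory reference

The vertical GRF is low-pass FIR filtered (30 Hz, Kaiser design, ≥60 dB
stopband, zero-phase), gated at 30 N, and de-glitched with a 0.2 s
duration gate applied to both short loaded runs (spurious contacts) and
short unloaded runs (spurious unloading); both gates are logged
separately, reading the one ambiguous gating sentence of the source
method as two rules.  Because even zero-phase filtering smears a loading
edge symmetrically, each stance edge is refined to the *raw* force's
threshold crossing within the filter's smear width — on ideal rectangular
pulses events are then exact to one 1 kHz sample, and on realistic
profiles the residual offset (~1–2 ms) is constant and cancels in every
duration.  Strides whose expected swing shows no unloaded span on their
own plate (stepping across the belt gap merges stances) are excluded, and
a trial with fewer than ten valid strides is excluded — that operational
reading of the "stepped in the middle of the treadmill" rule is isolated
behind `flag_contaminated_strides`.  Marker stride length adds belt
travel to the anterior–posterior marker displacement between ICs.  Stride
height is the swing maximum above the marker height at a marker-side
mid-stance proxy (minimum vertical marker speed within stance — the
reference system has no gyroscope to apply the sensor-side MST rule).
Stride width is the maximum perpendicular deviation from the stride's
ordinary least-squares line (lateral on AP); a path with no AP extent
falls back to deviation from the mean lateral level.

## Validation statistics

Errors are sensor − reference per gait cycle, paired by nearest IC
(greedy; equal to the optimal assignment on well-separated gait, which a
test verifies against `linear_sum_assignment`).  Cohort summaries average
per subject-side first.  Relative error = mean error / mean reference
value, not reported for event timings (not parameters) nor for stride
width/height (near-zero denominators).  Bland–Altman: bias ± 1.96·SD with
the sample SD (n−1); both pooled-cycle and subject-mean variants are
available (`pooled=` flag) since both conventions appear in the
literature.  Rank tests (Wilcoxon, Friedman) are routine statistics
available from scipy/pingouin and are deliberately out of scope here.

## Synthetic treadmill world

The simulator produces IMU, force-plate and marker streams from one
analytic kinematic model with closed-form derivatives, so every stream is
mutually consistent and all events/parameters are known exactly.  Presets
encode the four validated regimes (0.3, 0.5, preferred ≈ 0.76 m/s for the
patient cohort; 0.5 m/s controls) with their measured stride durations,
swing percentages, stride heights/widths and intra-subject duration
variability; stride length on a fixed-speed treadmill is
belt_speed × stride duration by construction.  Defaults worth knowing:

* lognormal cycle-duration jitter at the measured intra-subject CV
  (2.9–5.6% depending on regime); both sides share one anti-phase cycle
  clock so step and double-support timing stay physiological;
* consumer-MEMS noise: accelerometer SD 0.05 m/s², gyroscope SD
  0.005 rad/s, gyroscope bias 0.01 rad/s in a random fixed direction;
* a 2 s quasi-static standing lead-in (orientation init and bias
  estimation), with the plates unloaded until the first contact;
* landing/push-off transients are *displacement* wavelets (Gaussian ×
  45 Hz cosine) centred exactly on the true IC/FC, so the ay features the
  detector keys on coincide with the vGRF onsets — the two measurement
  systems observe the same physical contact — while adding only
  micrometres of true displacement;
* the shank rotation profile is a sum of smooth bumps (landing, two
  stance flanks, push-off, swing) whose areas are fixed rotation budgets
  (0.9 rad per cycle), producing the canonical ωz shape: dominant MSW
  peak, IC/FC troughs, quiet mid-stance.  True MST is the minimum
  |rotation rate| over the planted stance, i.e. minimum foot speed, which
  is also where the detector's stance-maximum rule fires;
* the ankle stays planted (belt-fixed) through stance, then advances by a
  minimum-jerk profile whose acceleration peaks exactly at FC (pre-swing
  heel rise), with a sin³ vertical arc and lateral half-wave.

What a green synthetic test does **not** establish: performance on real
skin-mounted sensors (soft-tissue artefact, mounting misalignment,
magnetic disturbance is moot but temperature-dependent bias drift is
not), real pathological variability beyond the qualitative overlays
(drop-foot, asymmetry, ataxia), overground or turning gait, or
synchronization error between measurement systems — in the validated
setting that last term dominated event-timing errors, and it is absent
here by construction.  The generator's world is deliberately the *easy*
version of the measurement problem; published error magnitudes are
therefore used as upper bounds, not as values to reproduce.

## Known limitations

* The width estimate carries a small positive bias (~3 mm) from lateral
  boundary-velocity components induced by frontal-plane wobble at MST;
  it stays within the accepted spatial bias envelope but is visible.
* `T_cycle` assumes a single dominant gait rhythm; festinating or highly
  irregular cadences violate the single-peak premise.
* The per-stride 0.0002 Hz high-pass is faithful to the published recipe
  but nearly inert on stride-length scales; its benefit on real long
  strides likely came from application to longer signal stretches.
* Event times are sample-resolution by design; sub-sample interpolation
  would be straightforward but is intentionally omitted.
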