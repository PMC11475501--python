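# Methods

## Movement-correctness pipeline

### Joint angles from 2-D keypoints

Each angle channel is the included angle at a vertex landmark between two
rays, `θ = arccos(v₁·v₂ / (|v₁||v₂|))` in degrees, with the cosine clamped
to [−1, 1] so floating-point noise near collinearity can never raise a
domain error. The six channels are built from ten landmarks
(left/right shoulder, hip, knee, ankle, foot_index):

| channel | vertex | rays | interpretation |
|---|---|---|---|
| shoulder-hip | hip | hip→shoulder, hip→knee | trunk–thigh angle |
| hip-knee | knee | knee→hip, knee→ankle | knee flexion |
| knee-ankle | ankle | ankle→knee, ankle→foot_index | ankle angle |

The three-point construction behind each named channel is a convention,
held in `AngleDefinition` configuration so alternates can be swapped in.
Because the included angle is invariant under translation, rotation,
reflection and uniform scaling of the image plane, pixel and normalised
coordinates are interchangeable and no camera calibration is attempted.
Angles are 2-D (single camera); no depth correction is applied, and
view-angle effects are out of scope.

A landmark with visibility below 0.5 (default) makes the frame's angle a
missing value rather than a fabricated number; interior missing runs of at
most `max_gap_frames` (default 3) are linearly interpolated, while longer
or edge runs stay missing and later veto any window that touches them.

### Windowing and the 60 features

Channels are cut into 30-sample windows stepped by 15 (50 % overlap); only
complete windows are used, giving `floor((N − 30)/15) + 1` windows for N ≥
30 samples. Per channel and window, ten statistics: Mean, Min, Max, Std,
Median of the angles, and the same five statistics of the Welch power
spectral density restricted to 1–20 Hz. Six channels × 10 = 60 feature
columns, named `Mean`, …, `Power_Median` with positional suffixes
(`.1` … `.5`) in the order left shoulder-hip, left hip-knee, left
knee-ankle, right shoulder-hip, right hip-knee, right knee-ankle.

Numerical conventions, chosen once and applied uniformly:

* Std uses the population denominator (n).
* Welch PSD: Hann taper, constant detrend, segment length equal to the
  30-sample window with 50 % inner overlap — a 30-sample window is too
  short to subdivide into several averaged periodograms, so this reduces
  to a single tapered periodogram, which is the sensible limit.
* At 30 fps the Nyquist frequency is 15 Hz, so the nominal 1–20 Hz band is
  clipped to [1, fs/2]; the clipping is mathematically forced and logged.
* Windows are labelled at trial level: every window of a correct trial is
  a "correct" sample.

### Per-movement classification and LOOCV

Each movement gets its own binary classifier over the feature columns of
its discriminative channel(s): M1/M4/M7 left knee-ankle, M2 left hip-knee,
M3/M6/M9 left shoulder-hip, M8 left + right shoulder-hip (20 columns); M5,
the stand-up, has no classifier. Features are z-scored, projected onto the
smallest number of principal components reaching 95 % explained variance
(minimum 2; zero-variance columns are dropped with a diagnostic), and
classified with an RBF SVM (C = 1.0, kernel width 1/(d·Var(X)),
scikit-learn's "scale"). The SVM hyper-parameters and the retained
component count are configuration, not claims about optimality.

Evaluation is leave-one-out over feature windows, matching the per-window
supports of the report tables. Standardisation and PCA are re-fitted
inside every training fold so the held-out row never influences
preprocessing; a `fold_hook` exposes fold internals for leakage checks. A
leave-one-trial-out mode is provided because overlapping windows of one
trial are temporally correlated, making window-level LOOCV optimistic on
real data; the default remains window-level to match per-window supports.
Reports carry per-class precision/recall/F1/support (0 = incorrect,
1 = correct), overall accuracy, macro and weighted averages; the mean
accuracy across movements is the unweighted mean of the per-movement
accuracies.

## IMU stability pipeline

Quaternions are Hamilton, scalar-first (w, x, y, z), mapping sensor→earth
via `a_e = q ⊗ a_s ⊗ q*` — the convention WT901-class sensors stream.
Inputs are normalised, with a warning when |q| deviates from 1 by more
than 1e-3; a zero quaternion is an error. Acceleration is in g by
default; the RMS comparison only requires unit consistency within a run.

The stability score of a trial is the RMS of `√(a_x² + a_y²)` in the earth
frame over its active samples. Gravity lies on earth Z and is untouched:
the metric deliberately excludes the vertical axis, where acceleration is
dominated by movement vigour rather than balance, so no gravity
subtraction is needed. Stationary samples are excluded either by
annotation intervals (mirroring video-based exclusion; the default) or by
an automatic detector flagging samples whose 0.5 s sliding std of |a_s|
falls below 0.02 g — a convenience whose threshold is configuration.

Paired comparison: scores are paired by (participant, movement), grouped
by posture (seated M1–M4, stand-up M5, standing M6–M9), and the
modified−regular differences are summarised by their median and tested
with a two-sided paired Wilcoxon signed-rank test (exact null distribution
at small n). The signed-rank test is the package's default because the
design is paired and RMS differences are not plausibly normal; the test
name is always printed with the result. At least 5 complete pairs per
group are required.

## Synthetic data

The generator produces exactly what the pipelines consume, with known
ground truth.

**Keypoint trials.** Each movement drives its discriminative channel(s)
with `baseline + A·sin(2πft) + ε`, ε ~ N(0, σ²); undriven channels sit at
resting baselines (shoulder-hip 100°, hip-knee 90°, knee-ankle 90°) plus
the same noise. Landmarks come from planar forward kinematics of a
shoulder–hip–knee–ankle–foot chain per side (trunk 0.50, thigh 0.45,
shank 0.45, foot 0.20 image units), built so the included angles equal the
requested trajectories exactly; the noiseless round trip through angle
extraction recovers the trajectory to < 0.5°. Defaults: 30 fps, 10 s
trials, f = 0.5 Hz (five repetitions per trial), σ = 2°, correct amplitude
40° vs incorrect 15° — incorrect execution is modelled as reduced range of
motion, the dominant failure mode in unsupervised training; templates are
explicit so other failure modes (tempo change, asymmetry) can be added. A
template whose deterministic trajectory leaves [0°, 180°] is rejected;
noise excursions are clipped at the boundary.

**IMU trials.** The earth-frame signal is a quadrature pair of horizontal
sinusoids of amplitude A (plus a vertical ripple on top of 1 g), active
between one-second rest edges; orientation is either a random static
quaternion or a slow tilt. Sensor-frame samples are built with the exact
inverse rotation `a_s = q* ⊗ a_e ⊗ q` plus N(0, 0.005 g) noise, so the
analysis transform recovers a_e identically in the noiseless case. The
quadrature pair makes the noiseless horizontal magnitude constant at A,
giving a closed-form ground-truth RMS. Defaults: 50 Hz, 12 s, f = 1 Hz,
A = 0.05 g for the modified chair vs 0.10 g for the regular chair — a 2×
sway gap; ten participants with both conditions per movement.

**Default dataset scale.** 8 classified movements × 20 trials per class
(320 keypoint trials → 6080 feature windows) and 10 × 9 × 2 IMU trials.
These sizes keep a full end-to-end run around a minute on one CPU while
leaving LOOCV supports in the hundreds per movement, comparable to the
per-movement window counts of a real study.

**What the generator does not emulate.** Pose-estimator artefacts beyond
additive jitter (occlusion, identity swaps, lighting), perspective
distortion, within-trial tempo drift, correlated sensor noise, gyro drift
in the quaternions, and between-participant variability in body geometry.
Passing tests therefore demonstrate that the pipeline recovers the
quantities it defines under its stated model — not that the classifier
accuracies or significance levels would transfer to field recordings.

## Degenerate inputs and tie-breaks

* Zero-length angle rays → NaN (missing), never an exception mid-stream.
* Series shorter than one window → zero windows plus a warning.
* A feature column with zero variance in a training fold is dropped in
  that fold only.
* All-identical paired RMS values short-circuit to p = 1 ("no
  difference") rather than invoking the signed-rank test with no nonzero
  differences.
* CSV floats are written with `repr` so writes are byte-stable and round
  trips are exact.

## Known limitations

Window-level LOOCV shares a trial's windows between train and test folds;
use `cv_mode="trial"` for the conservative estimate. The 1–20 Hz band is
aspirational at 30 fps (effective 1–15 Hz). The published study's raw
recordings are unavailable, so its significance levels and accuracies are
not reproduced here; the synthetic dataset checks internal correctness and
sensitivity, not field performance.
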