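# exerform

Tools for assessing chair-based resistance exercise in older adults from
two inexpensive sensing modalities:

1. **Movement correctness from video pose keypoints.** A 2-D pose
   estimator (e.g. MediaPipe on ordinary 30 fps video) emits per-frame
   body landmarks. `exerform` converts them into six joint-angle channels
   (left/right shoulder-hip, hip-knee, knee-ankle), windows each channel
   (30 samples, 15-sample overlap) and extracts 60 features — per channel
   the Mean, Min, Max, Std and Median of the angles plus the same five
   statistics of the Welch power spectrum in a 1–20 Hz band. A
   per-movement classifier (channel screening → z-scoring → PCA → RBF
   SVM) then labels each window *correct* (1) or *incorrect* (0), and is
   evaluated by leave-one-out cross-validation with all preprocessing
   fitted inside each training fold.
2. **Body stability from a chest-worn IMU.** Sensor-frame acceleration is
   rotated into the earth frame with the sensor's orientation quaternion,
   `a_e = q ⊗ a_s ⊗ q*`, gravity stays on earth Z, and stability is scored
   as `RMS(√(a_x² + a_y²))` over the non-stationary part of the trial —
   lower is steadier. Scores are paired by participant and movement and
   the modified chair is compared against a regular armless chair with a
   paired Wilcoxon signed-rank test per posture group (seated M1–M4,
   stand-up M5, standing M6–M9).

The nine movements M1–M9 are the standard chair-based lower-limb
resistance exercises; the stand-up movement M5 has no correctness
classifier. A synthetic-data module generates keypoint and IMU trials
with known ground truth (planar forward kinematics driven by sinusoidal
joint angles; earth-frame IMU signals inverted into the sensor frame), so
the whole pipeline is testable without any recordings.

## Worked example

```python
import exerform as ef

# a small synthetic study: 8 movements, 3 trials per class
cfg = ef.DatasetConfig(trials_per_class=3, imu_subjects=6)
bundle = ef.generate_dataset(cfg, seed=7)

table = ef.extract_features(bundle.keypoint_streams, bundle.labels)
res = ef.MovementCorrectnessModel(table, "M1").fit()
print(res.summary())

scored = [ef.stability_score(s) for s in bundle.imu_streams]
print(ef.ChairStabilityModel([r for r in scored if r]).fit().summary())
```

prints

```
Movement correctness model — M1
rows: 114; channels: left_knee_ankle; cv: leave-one-window-out; PCA components: 4 (99.5% var)
Average Accuracy 1: 100.0000%
               Precision    Recall  F1-score   Support
0                   1.00      1.00      1.00        57
1                   1.00      1.00      1.00        57
Accuracy                                1.00       114
Macro Avg           1.00      1.00      1.00       114
Weighted Avg        1.00      1.00      1.00       114

Chair-condition stability comparison (RMS of horizontal acceleration)
test: Wilcoxon signed-rank (paired, two-sided); negative diff = modified steadier
group      n_pairs   median_diff     p_value  direction
seated          24     -0.049605   1.192e-07  modified < regular
stand_up         6      -0.04943     0.03125  modified < regular
standing        24     -0.049652   1.192e-07  modified < regular
```

Each movement report is the per-class precision/recall/F1/support of the
LOOCV predictions (class 0 = incorrect, 1 = correct) with the overall
accuracy as a percent header. The stability table shows, per posture
group, the median modified−regular difference in RMS horizontal
acceleration (in g): here the modified chair halves the synthetic sway
amplitude, so every group shows `modified < regular` at p < 0.05.

The same pipelines are available from the shell:

```bash
exerform simulate --seed 7 --out data/
exerform evaluate data/keypoints data/labels.csv --out reports/
exerform stability data/imu data/segments.csv --out stability/
```

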