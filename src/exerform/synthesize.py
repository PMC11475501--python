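"""Synthetic movement and IMU trials with known ground truth.

The generator emulates chair-based resistance exercise recordings at the
level the analysis pipeline consumes them:

* **Keypoint streams** — each movement drives one or two joint-angle
  channels with a sinusoid, ``baseline + amplitude·sin(2πft) + noise``;
  incorrect executions differ from correct ones by a reduced range of
  motion (smaller amplitude). Per-frame landmark positions are produced by
  planar forward kinematics of a four-segment side chain
  (shoulder–hip–knee–ankle–foot_index), so re-deriving angles from the
  keypoints recovers the generating trajectories exactly in the noiseless
  case.
* **IMU streams** — an earth-frame acceleration signal with per-condition
  horizontal amplitude (the modified chair halves body sway in the default
  scenario), gravity on Z, and a known orientation trajectory q(t); the
  sensor-frame samples are constructed with the inverse rotation
  a_s = q* ⊗ a_e ⊗ q, so the analysis transform recovers a_e. The
  ground-truth horizontal RMS is computed from the noiseless earth-frame
  signal over the active schedule.

All randomness flows from one integer seed through ``numpy`` generators;
``generate_dataset`` is byte-reproducible from (config, seed) and records
every ground-truth parameter in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .angles import CHANNEL_ORDER
from .keypoints import (
    CLASSIFIED_MOVEMENTS,
    KeypointFrame,
    KeypointStream,
    Landmark,
    TrialLabel,
    write_keypoint_stream,
    write_trial_labels,
)
from .imu import IMUStream, rms, horizontal_magnitude, rotate_to_sensor, write_imu_csv, write_segments_csv

__all__ = [
    "BodyModel",
    "MovementTemplate",
    "IMUScenario",
    "DatasetConfig",
    "DatasetBundle",
    "DEFAULT_TEMPLATES",
    "DEFAULT_IMU_SCENARIO",
    "simulate_movement_trial",
    "simulate_imu_trial",
    "generate_dataset",
]

#: Resting angle (degrees) of each channel type when it is not driven.
_BASELINES = {"shoulder_hip": 100.0, "hip_knee": 90.0, "knee_ankle": 90.0}


@dataclass(frozen=True)
class BodyModel:
    """Planar segment lengths (arbitrary image units) and hip root positions."""

    trunk: float = 0.50
    thigh: float = 0.45
    shank: float = 0.45
    foot: float = 0.20
    hip_left: tuple[float, float] = (0.45, 0.50)
    hip_right: tuple[float, float] = (0.55, 0.50)

    def __post_init__(self):
        for name in ("trunk", "thigh", "shank", "foot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be positive")


@dataclass(frozen=True)
class MovementTemplate:
    """Periodic joint-angle trajectory for one movement."""

    movement: str
    driven: tuple[str, ...]
    baseline_deg: float = 90.0
    amplitude_correct_deg: float = 40.0
    amplitude_incorrect_deg: float = 15.0
    frequency_hz: float = 0.5
    noise_std_deg: float = 2.0
    duration_s: float = 10.0
    fps: float = 30.0

    def amplitude(self, correctness: str) -> float:
        return self.amplitude_correct_deg if correctness == "correct" else self.amplitude_incorrect_deg

    def validate(self) -> None:
        if self.frequency_hz >= self.fps / 2:
            raise ValueError(f"{self.movement}: frequency {self.frequency_hz} Hz >= Nyquist")
        for corr in ("correct", "incorrect"):
            amp = self.amplitude(corr)
            if not (0.0 < self.baseline_deg - amp and self.baseline_deg + amp < 180.0):
                raise ValueError(
                    f"{self.movement}: baseline {self.baseline_deg}° ± {amp}° leaves [0, 180]"
                )


def _template(movement: str, driven: tuple[str, ...]) -> MovementTemplate:
    kind = driven[0].split("_", 1)[1]
    return MovementTemplate(movement=movement, driven=driven, baseline_deg=_BASELINES[kind])


#: One template per movement; driven channels follow the per-movement
#: discriminative-channel map (M5, the stand-up, drives trunk + knee).
DEFAULT_TEMPLATES: dict[str, MovementTemplate] = {
    "M1": _template("M1", ("left_knee_ankle",)),
    "M2": _template("M2", ("left_hip_knee",)),
    "M3": _template("M3", ("left_shoulder_hip",)),
    "M4": _template("M4", ("left_knee_ankle",)),
    "M5": _template("M5", ("left_shoulder_hip", "left_hip_knee")),
    "M6": _template("M6", ("left_shoulder_hip",)),
    "M7": _template("M7", ("left_knee_ankle",)),
    "M8": _template("M8", ("left_shoulder_hip", "right_shoulder_hip")),
    "M9": _template("M9", ("left_shoulder_hip",)),
}


# ---------------------------------------------------------------------------
# Forward kinematics


def _unit(theta_rad: np.ndarray) -> np.ndarray:
    return np.stack([np.cos(theta_rad), np.sin(theta_rad)], axis=-1)


def _chain_points(
    hip: np.ndarray,
    theta_sh: np.ndarray,
    theta_hk: np.ndarray,
    theta_ka: np.ndarray,
    body: BodyModel,
) -> dict[str, np.ndarray]:
    """Place shoulder/knee/ankle/foot so the three channel angles are exact.

    The trunk points straight up in image coordinates; each subsequent
    segment direction is rotated clockwise by the channel angle off the
    reversed parent segment, which makes the included angle at each vertex
    equal to the requested channel value for angles in (0, 180).
    """
    d_sh = np.full_like(theta_sh, np.pi / 2)  # hip→shoulder, fixed "up"
    shoulder = hip + body.trunk * _unit(d_sh)
    d_hk = d_sh - np.radians(theta_sh)  # hip→knee
    knee = hip + body.thigh * _unit(d_hk)
    d_ka = (d_hk + np.pi) - np.radians(theta_hk)  # knee→ankle
    ankle = knee + body.shank * _unit(d_ka)
    d_kf = (d_ka + np.pi) - np.radians(theta_ka)  # ankle→foot_index
    foot = ankle + body.foot * _unit(d_kf)
    return {"shoulder": shoulder, "hip": hip, "knee": knee, "ankle": ankle, "foot_index": foot}


def simulate_movement_trial(
    template: MovementTemplate,
    body: BodyModel = BodyModel(),
    correctness: str = "correct",
    seed: int = 0,
    trial_id: str | None = None,
    condition: str = "modified",
    subject: str | None = None,
    landmark_jitter: float = 0.0,
) -> tuple[KeypointStream, TrialLabel]:
    """Generate one labelled keypoint trial from a movement template.

    Returns the stream together with its trial label. With zero noise the
    driven channel's angle trajectory is recovered by the angle pipeline to
    well under half a degree.
    """
    template.validate()
    rng = np.random.default_rng(seed)
    n = int(round(template.duration_s * template.fps))
    t = np.arange(n) / template.fps
    amp = template.amplitude(correctness)

    traj: dict[str, np.ndarray] = {}
    for ch in CHANNEL_ORDER:
        kind = ch.split("_", 1)[1]
        base = template.baseline_deg if ch in template.driven else _BASELINES[kind]
        a = amp if ch in template.driven else 0.0
        series = base + a * np.sin(2 * np.pi * template.frequency_hz * t)
        if template.noise_std_deg > 0:
            series = series + rng.normal(0.0, template.noise_std_deg, size=n)
        traj[ch] = np.clip(series, 0.1, 179.9)

    points: dict[str, np.ndarray] = {}
    for side, hip_root in (("left", body.hip_left), ("right", body.hip_right)):
        hip = np.tile(np.asarray(hip_root, dtype=float), (n, 1))
        chain = _chain_points(
            hip,
            traj[f"{side}_shoulder_hip"],
            traj[f"{side}_hip_knee"],
            traj[f"{side}_knee_ankle"],
            body,
        )
        for part, xy in chain.items():
            points[f"{side}_{part}"] = xy
    if landmark_jitter > 0:
        for name in points:
            points[name] = points[name] + rng.normal(0.0, landmark_jitter, size=points[name].shape)

    frames = []
    for i in range(n):
        lms = {
            name: Landmark(name, float(xy[i, 0]), float(xy[i, 1]), 1.0)
            for name, xy in points.items()
        }
        frames.append(KeypointFrame(frame_index=i, time_s=float(t[i]), landmarks=lms))

    tid = trial_id or f"{template.movement}-{correctness}-s{seed}"
    stream = KeypointStream(
        trial_id=tid,
        movement=template.movement,
        frames=frames,
        fps=template.fps,
        condition=condition,
        correctness_label=correctness,
        subject=subject,
    )
    label = TrialLabel(tid, template.movement, correctness, condition, subject)
    return stream, label


# ---------------------------------------------------------------------------
# IMU scenario


@dataclass(frozen=True)
class IMUScenario:
    """Earth-frame signal generators and orientation trajectory for one trial.

    ``amp_xy_g`` gives the horizontal sway amplitude per chair condition in
    g; the default scenario gives the regular chair twice the sway of the
    modified one. The rest/move schedule leaves one second of stationary
    sitting at each end of the trial.
    """

    fs: float = 50.0
    duration_s: float = 12.0
    freq_hz: float = 1.0
    amp_xy_g: dict[str, float] = field(
        default_factory=lambda: {"modified": 0.05, "regular": 0.10}
    )
    amp_z_g: float = 0.05
    gravity_g: float = 1.0
    noise_std_g: float = 0.005
    orientation: str = "static"  # "static" | "tilt"
    tilt_deg: float = 15.0
    tilt_freq_hz: float = 0.05
    rest_edge_s: float = 1.0

    def active_segments(self) -> list[tuple[float, float]]:
        return [(self.rest_edge_s, self.duration_s - self.rest_edge_s)]


DEFAULT_IMU_SCENARIO = IMUScenario()


def _random_unit_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _orientation_trajectory(scenario: IMUScenario, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if scenario.orientation == "static":
        return np.tile(_random_unit_quat(rng), (len(t), 1))
    if scenario.orientation == "tilt":
        half = 0.5 * np.radians(scenario.tilt_deg) * np.sin(2 * np.pi * scenario.tilt_freq_hz * t)
        return np.stack([np.cos(half), np.sin(half), np.zeros_like(t), np.zeros_like(t)], axis=-1)
    raise ValueError(f"unknown orientation mode {scenario.orientation!r}")


def simulate_imu_trial(
    scenario: IMUScenario,
    condition: str = "modified",
    seed: int = 0,
    movement: str = "M1",
    trial_id: str | None = None,
    subject: str | None = None,
) -> tuple[IMUStream, float]:
    """Generate one IMU trial; returns the stream and the ground-truth
    horizontal RMS of the noiseless earth-frame signal over active samples."""
    if condition not in scenario.amp_xy_g:
        raise ValueError(f"scenario has no amplitude for condition {condition!r}")
    rng = np.random.default_rng(seed)
    n = int(round(scenario.duration_s * scenario.fs))
    t = np.arange(n) / scenario.fs
    segments = scenario.active_segments()
    active = np.zeros(n, dtype=bool)
    for t0, t1 in segments:
        active |= (t >= t0) & (t < t1)

    amp = scenario.amp_xy_g[condition]
    a_e = np.zeros((n, 3))
    a_e[:, 0] = amp * np.sin(2 * np.pi * scenario.freq_hz * t) * active
    a_e[:, 1] = amp * np.sin(2 * np.pi * scenario.freq_hz * t + np.pi / 2) * active
    a_e[:, 2] = scenario.gravity_g + scenario.amp_z_g * np.sin(2 * np.pi * 2 * scenario.freq_hz * t) * active

    quat = _orientation_trajectory(scenario, t, rng)
    norms = np.linalg.norm(quat, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("orientation trajectory is not unit-norm")
    a_s = rotate_to_sensor(a_e, quat)
    if scenario.noise_std_g > 0:
        a_s = a_s + rng.normal(0.0, scenario.noise_std_g, size=a_s.shape)

    gt_rms = rms(horizontal_magnitude(a_e[active]))
    tid = trial_id or f"imu-{movement}-{condition}-s{seed}"
    stream = IMUStream(
        trial_id=tid,
        movement=movement,
        condition=condition,
        time_s=t,
        accel=a_s,
        quat=quat,
        active_segments=segments,
        subject=subject,
    )
    return stream, gt_rms


# ---------------------------------------------------------------------------
# Full dataset


@dataclass(frozen=True)
class DatasetConfig:
    """Study-scale synthetic dataset: which movements, how many trials."""

    movements: tuple[str, ...] = CLASSIFIED_MOVEMENTS
    trials_per_class: int = 20
    body: BodyModel = BodyModel()
    imu_subjects: int = 10
    imu_movements: tuple[str, ...] = tuple(f"M{i}" for i in range(1, 10))
    imu_scenario: IMUScenario = DEFAULT_IMU_SCENARIO

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")


@dataclass
class DatasetBundle:
    keypoint_streams: list[KeypointStream]
    labels: list[TrialLabel]
    imu_streams: list[IMUStream]
    imu_ground_truth: dict[str, float]
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "keypoints").mkdir(parents=True, exist_ok=True)
        (out / "imu").mkdir(parents=True, exist_ok=True)
        for s in self.keypoint_streams:
            write_keypoint_stream(s, out / "keypoints" / f"{s.trial_id}.csv")
        write_trial_labels(self.labels, out / "labels.csv")
        segments: dict[str, list[tuple[float, float]]] = {}
        for s in self.imu_streams:
            write_imu_csv(s, out / "imu" / f"{s.trial_id}.csv")
            segments[s.trial_id] = list(s.active_segments)
        write_segments_csv(segments, out / "segments.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True) + "\n")
        return out


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def generate_dataset(
    config: DatasetConfig = DatasetConfig(),
    seed: int = 0,
    templates: dict[str, MovementTemplate] | None = None,
) -> DatasetBundle:
    """Generate the full labelled bundle: keypoint trials for every movement
    and class, plus paired IMU trials for every (subject, movement).

    Deterministic: per-trial seeds are spawned from the master seed, so the
    same (config, seed) yields an identical bundle.
    """
    templates = templates or DEFAULT_TEMPLATES
    root = np.random.SeedSequence(seed)
    streams: list[KeypointStream] = []
    labels: list[TrialLabel] = []
    manifest: dict = {
        "seed": seed,
        "config": _as_jsonable(config),
        "templates": {m: _as_jsonable(templates[m]) for m in config.movements},
        "trials": {},
    }

    kp_seeds = iter(root.spawn(len(config.movements) * 2 * config.trials_per_class))
    for movement in config.movements:
        tpl = templates[movement]
        for correctness in ("correct", "incorrect"):
            for k in range(config.trials_per_class):
                child = next(kp_seeds)
                trial_seed = int(child.generate_state(1)[0] % (2**31))
                tid = f"{movement}-{correctness}-{k:03d}"
                stream, label = simulate_movement_trial(
                    tpl, config.body, correctness, seed=trial_seed, trial_id=tid
                )
                streams.append(stream)
                labels.append(label)
                manifest["trials"][tid] = {
                    "movement": movement,
                    "correctness": correctness,
                    "seed": trial_seed,
                    "amplitude_deg": tpl.amplitude(correctness),
                }

    imu_streams: list[IMUStream] = []
    gt: dict[str, float] = {}
    imu_seeds = iter(root.spawn(config.imu_subjects * len(config.imu_movements) * 2))
    for s_idx in range(config.imu_subjects):
        subject = f"S{s_idx:02d}"
        for movement in config.imu_movements:
            for condition in ("modified", "regular"):
                child = next(imu_seeds)
                trial_seed = int(child.generate_state(1)[0] % (2**31))
                tid = f"imu-{subject}-{movement}-{condition}"
                stream, true_rms = simulate_imu_trial(
                    config.imu_scenario, condition, seed=trial_seed,
                    movement=movement, trial_id=tid, subject=subject,
                )
                imu_streams.append(stream)
                gt[tid] = true_rms
                manifest["trials"][tid] = {
                    "movement": movement,
                    "condition": condition,
                    "subject": subject,
                    "seed": trial_seed,
                    "true_rms_xy": true_rms,
                }
    return DatasetBundle(streams, labels, imu_streams, gt, manifest)
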