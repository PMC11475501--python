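"""IMU-based body-stability scoring and chair-condition comparison.

A chest-worn inertial sensor streams triaxial acceleration in its own
(sensor) frame together with a unit quaternion q giving the sensor→earth
orientation. Stability analysis works in the earth frame:

    a_e = q ⊗ a_s ⊗ q*          (Hamilton product, scalar-first quaternions)

where q* is the conjugate. Gravity then lies along earth Z, so the
horizontal composite acceleration sqrt(ax² + ay²) isolates side-to-side
body sway; its root mean square over the active (non-stationary) part of a
trial is the stability score — lower means steadier. Z is excluded because
vertical accelerations are dominated by how vigorously a participant moves,
not by loss of balance.

Stationary stretches are masked out either from an annotation file of
active intervals (mirroring video-based exclusion) or by an automatic
detector that flags samples where a sliding-window standard deviation of
|a_s| falls below a threshold.

Condition comparison (modified vs regular chair) is paired by
(subject, movement) and summarised per posture group — seated M1–M4,
stand-up M5, standing M6–M9 — with a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IMUStream",
    "StabilityResult",
    "MOVEMENT_GROUPS",
    "quat_conjugate",
    "quat_multiply",
    "rotate_to_earth",
    "rotate_to_sensor",
    "horizontal_magnitude",
    "rms",
    "mask_active",
    "stability_score",
    "compare_conditions",
    "ChairStabilityModel",
    "StabilityResults",
    "read_imu_csv",
    "write_imu_csv",
    "read_segments_csv",
    "write_segments_csv",
]

log = logging.getLogger(__name__)

#: Posture groups used when summarising the chair comparison.
MOVEMENT_GROUPS: dict[str, tuple[str, ...]] = {
    "seated": ("M1", "M2", "M3", "M4"),
    "stand_up": ("M5",),
    "standing": ("M6", "M7", "M8", "M9"),
}


# ---------------------------------------------------------------------------
# Quaternion algebra (Hamilton convention, scalar-first w,x,y,z)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q, broadcasting over leading axes."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = (p[..., i] for i in range(4))
    qw, qx, qy, qz = (q[..., i] for i in range(4))
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def _normalized(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise ValueError("zero quaternion is not a valid orientation")
    if np.any(np.abs(norm - 1.0) > 1e-3):
        log.warning("quaternion norm deviates from 1 by > 1e-3; renormalising")
    return q / norm


def rotate_to_earth(a_s: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame vectors into the earth frame: a_e = q ⊗ a_s ⊗ q*.

    ``a_s`` may be a single 3-vector or an (N, 3) array; ``q`` broadcasts the
    same way. Quaternions are normalised before use; vector norms are
    preserved to machine precision.
    """
    a_s = np.asarray(a_s, dtype=float)
    q = _normalized(q)
    pure = np.concatenate([np.zeros(a_s.shape[:-1] + (1,)), a_s], axis=-1)
    rotated = quat_multiply(quat_multiply(q, pure), quat_conjugate(q))
    return rotated[..., 1:]


def rotate_to_sensor(a_e: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Inverse transform, earth → sensor: a_s = q* ⊗ a_e ⊗ q."""
    return rotate_to_earth(a_e, quat_conjugate(_normalized(q)))


# ---------------------------------------------------------------------------
# Scalar metrics


def horizontal_magnitude(a_e: np.ndarray) -> np.ndarray:
    """Per-sample composite horizontal acceleration sqrt(ax² + ay²); Z ignored."""
    a_e = np.asarray(a_e, dtype=float)
    return np.hypot(a_e[..., 0], a_e[..., 1])


def rms(series: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x²))."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty series is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# Streams


@dataclass
class IMUStream:
    """Timestamped sensor-frame acceleration + orientation for one trial."""

    trial_id: str
    movement: str
    condition: str
    time_s: np.ndarray
    accel: np.ndarray  # (N, 3) sensor frame, g units by default
    quat: np.ndarray  # (N, 4) scalar-first sensor→earth
    active_segments: list[tuple[float, float]] = field(default_factory=list)
    subject: str | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.accel.shape != (len(self.time_s), 3):
            raise ValueError(f"accel shape {self.accel.shape} != ({len(self.time_s)}, 3)")
        if self.quat.shape != (len(self.time_s), 4):
            raise ValueError(f"quat shape {self.quat.shape} != ({len(self.time_s)}, 4)")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def earth_accel(self) -> np.ndarray:
        return rotate_to_earth(self.accel, self.quat)


@dataclass(frozen=True)
class StabilityResult:
    trial_id: str
    movement: str
    condition: str
    rms_xy: float
    n_samples_used: int
    subject: str | None = None


def mask_active(
    stream: IMUStream,
    auto: bool = False,
    window_s: float = 0.5,
    std_threshold: float = 0.02,
) -> np.ndarray:
    """Boolean mask of samples to score (True = active).

    With annotation-driven masking (default), a sample is active when its
    time lies in one of ``stream.active_segments`` (half-open [t0, t1)
    intervals). With ``auto=True`` a sample is stationary when the sliding
    standard deviation of |a_s| in a centred ``window_s`` window falls below
    ``std_threshold`` (same units as the acceleration stream).
    """
    if auto:
        mag = np.linalg.norm(stream.accel, axis=1)
        if len(stream.time_s) > 1:
            dt = float(np.median(np.diff(stream.time_s)))
        else:
            dt = 1.0
        win = max(3, int(round(window_s / dt)))
        rolling = pd.Series(mag).rolling(win, center=True, min_periods=1).std(ddof=0)
        return rolling.to_numpy() >= std_threshold
    mask = np.zeros(stream.n_samples, dtype=bool)
    for t0, t1 in stream.active_segments:
        mask |= (stream.time_s >= t0) & (stream.time_s < t1)
    return mask


def stability_score(
    stream: IMUStream,
    auto_mask: bool = False,
    **mask_kwargs,
) -> StabilityResult | None:
    """Score one trial: RMS of horizontal earth-frame acceleration over
    active samples. Returns None (with a warning) when no sample is active."""
    mask = mask_active(stream, auto=auto_mask, **mask_kwargs)
    if not mask.any():
        log.warning("trial %s: no active samples, stability not scored", stream.trial_id)
        return None
    a_e = stream.earth_accel()[mask]
    return StabilityResult(
        trial_id=stream.trial_id,
        movement=stream.movement,
        condition=stream.condition,
        rms_xy=rms(horizontal_magnitude(a_e)),
        n_samples_used=int(mask.sum()),
        subject=stream.subject,
    )


# ---------------------------------------------------------------------------
# Paired condition comparison


class PairingError(ValueError):
    pass


def _pair_table(results: Sequence[StabilityResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subject": [r.subject or r.trial_id for r in results],
            "movement": [r.movement for r in results],
            "condition": [r.condition for r in results],
            "rms_xy": [r.rms_xy for r in results],
        }
    )
    wide = df.pivot_table(
        index=["subject", "movement"], columns="condition", values="rms_xy", aggfunc="mean"
    )
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing:
        raise PairingError(f"unpaired results for (subject, movement): {missing}")
    for cond in ("modified", "regular"):
        if cond not in wide.columns:
            raise PairingError(f"no results for condition {cond!r}")
    return wide.reset_index()


def compare_conditions(
    results: Sequence[StabilityResult],
    groups: dict[str, tuple[str, ...]] = MOVEMENT_GROUPS,
    min_pairs: int = 5,
) -> dict[str, dict]:
    """Paired modified-vs-regular summary per posture group.

    For each group the modified−regular RMS differences over (subject,
    movement) pairs are summarised by their median and tested with a paired
    two-sided Wilcoxon signed-rank test (exact p for small n). Direction
    "modified < regular" means the modified chair is the steadier condition.
    """
    wide = _pair_table(results)
    out: dict[str, dict] = {}
    for group, movements in groups.items():
        sub = wide[wide["movement"].isin(movements)]
        if sub.empty:
            continue
        if len(sub) < min_pairs:
            raise PairingError(f"group {group!r}: only {len(sub)} pairs, need >= {min_pairs}")
        diff = (sub["modified"] - sub["regular"]).to_numpy()
        med = float(np.median(diff))
        if np.allclose(diff, 0.0):
            p = 1.0
            direction = "no difference"
        else:
            res = stats.wilcoxon(
                sub["modified"], sub["regular"], alternative="two-sided",
                zero_method="wilcox", mode="auto",
            )
            p = float(res.pvalue)
            direction = "modified < regular" if med < 0 else ("modified > regular" if med > 0 else "no difference")
        out[group] = {
            "n_pairs": int(len(sub)),
            "median_diff": med,
            "direction": direction,
            "p_value": p,
            "test": "Wilcoxon signed-rank (paired, two-sided)",
        }
    return out


class ChairStabilityModel:
    """Paired chair-condition stability comparison.

    Built from per-trial stability scores; ``fit()`` pairs trials by
    (subject, movement) and runs the signed-rank comparison per posture
    group.
    """

    def __init__(self, results: Sequence[StabilityResult], groups: dict[str, tuple[str, ...]] | None = None,
                 min_pairs: int = 5):
        if not results:
            raise ValueError("no stability results")
        self.results = list(results)
        self.groups = groups or MOVEMENT_GROUPS
        self.min_pairs = min_pairs

    @classmethod
    def from_streams(cls, streams: Iterable[IMUStream], auto_mask: bool = False, **kwargs):
        scored = [stability_score(s, auto_mask=auto_mask) for s in streams]
        return cls([r for r in scored if r is not None], **kwargs)

    def fit(self) -> "StabilityResults":
        return StabilityResults(model=self, comparisons=compare_conditions(self.results, self.groups, self.min_pairs))


@dataclass
class StabilityResults:
    model: ChairStabilityModel
    comparisons: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.comparisons, orient="index")

    def summary(self) -> str:
        lines = ["Chair-condition stability comparison (RMS of horizontal acceleration)"]
        lines.append("test: Wilcoxon signed-rank (paired, two-sided); negative diff = modified steadier")
        lines.append(f"{'group':<10}{'n_pairs':>8}{'median_diff':>14}{'p_value':>12}  direction")
        for group, c in self.comparisons.items():
            lines.append(
                f"{group:<10}{c['n_pairs']:>8d}{c['median_diff']:>14.5g}{c['p_value']:>12.4g}  {c['direction']}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV dialects


def write_imu_csv(stream: IMUStream, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": stream.time_s,
            "ax": stream.accel[:, 0],
            "ay": stream.accel[:, 1],
            "az": stream.accel[:, 2],
            "qw": stream.quat[:, 0],
            "qx": stream.quat[:, 1],
            "qy": stream.quat[:, 2],
            "qz": stream.quat[:, 3],
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"#trial_id={stream.trial_id}\n#movement={stream.movement}\n"
            f"#condition={stream.condition}\n#subject={stream.subject or ''}\n"
        )
        df.to_csv(fh, index=False)
    return path


def read_imu_csv(path: str | Path) -> IMUStream:
    import io

    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        k, v = line[1:].strip().split("=", 1)
        meta[k] = v
        body += 1
    try:
        df = pd.read_csv(io.StringIO("".join(lines[body:])))
    except Exception as exc:
        raise ValueError(f"{path}: malformed IMU CSV: {exc}") from exc
    needed = ["time_s", "ax", "ay", "az", "qw", "qx", "qy", "qz"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: IMU CSV missing columns {missing}")
    return IMUStream(
        trial_id=meta.get("trial_id", path.stem),
        movement=meta.get("movement", "M1"),
        condition=meta.get("condition", "modified"),
        time_s=df["time_s"].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        quat=df[["qw", "qx", "qy", "qz"]].to_numpy(),
        subject=meta.get("subject") or None,
    )


def read_segments_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Active-segment annotations: CSV ``trial_id,t_start,t_end`` → mapping."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        t0, t1 = float(row["t_start"]), float(row["t_end"])
        if t1 <= t0:
            raise ValueError(f"{path}: segment [{t0}, {t1}) is empty or inverted")
        out.setdefault(str(row["trial_id"]), []).append((t0, t1))
    for segs in out.values():
        segs.sort()
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if b0 < a1:
                raise ValueError(f"{path}: overlapping segments [{a0},{a1}) and [{b0},{b1})")
    return out


def write_segments_csv(segments: dict[str, list[tuple[float, float]]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["trial_id,t_start,t_end"]
    for trial_id, segs in segments.items():
        for t0, t1 in segs:
            lines.append(f"{trial_id},{t0!r},{t1!r}")
    path.write_text("\n".join(lines) + "\n")
    return path
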