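"""Joint-angle channels from 2-D keypoints.

Six channels are derived per trial, three per body side, each the angle at a
vertex landmark between two rays:

* ``shoulder_hip`` — at the hip, between hip→shoulder and hip→knee
  (trunk–thigh angle);
* ``hip_knee`` — at the knee, between knee→hip and knee→ankle (knee flexion);
* ``knee_ankle`` — at the ankle, between ankle→knee and ankle→foot_index.

The angle between two rays v1, v2 is arccos(v1·v2 / (|v1||v2|)) in degrees,
clamped into [-1, 1] before the arccos so floating-point noise near collinear
configurations cannot raise a domain error. The value is therefore always in
[0, 180] and is invariant under translation, rotation, reflection and uniform
scaling of the image plane — which is why pixel vs normalised coordinates
need not be distinguished.

Frames where a required landmark falls below the visibility threshold become
NaN rather than a fabricated angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AngleDefinition",
    "AngleSeries",
    "DEFAULT_ANGLE_DEFINITIONS",
    "CHANNEL_ORDER",
    "vector_angle",
    "compute_angle_channels",
    "interpolate_gaps",
    "write_angle_series",
    "read_angle_series",
]


@dataclass(frozen=True)
class AngleDefinition:
    """Three-point construction of one named angle channel."""

    channel_name: str
    vertex: str
    ray_a: str
    ray_b: str

    def __post_init__(self):
        if len({self.vertex, self.ray_a, self.ray_b}) != 3:
            raise ValueError(f"{self.channel_name}: vertex and rays must be distinct landmarks")


def _side_defs(side: str) -> list[AngleDefinition]:
    return [
        AngleDefinition(f"{side}_shoulder_hip", f"{side}_hip", f"{side}_shoulder", f"{side}_knee"),
        AngleDefinition(f"{side}_hip_knee", f"{side}_knee", f"{side}_hip", f"{side}_ankle"),
        AngleDefinition(f"{side}_knee_ankle", f"{side}_ankle", f"{side}_knee", f"{side}_foot_index"),
    ]


DEFAULT_ANGLE_DEFINITIONS: tuple[AngleDefinition, ...] = tuple(_side_defs("left") + _side_defs("right"))

#: Channel order used for feature-name suffixes: left side first, then right.
CHANNEL_ORDER: tuple[str, ...] = (
    "left_shoulder_hip",
    "left_hip_knee",
    "left_knee_ankle",
    "right_shoulder_hip",
    "right_hip_knee",
    "right_knee_ankle",
)


def vector_angle(p_a, p_vertex, p_b) -> float:
    """Angle in degrees at ``p_vertex`` between rays to ``p_a`` and ``p_b``.

    Returns NaN when either ray has zero length (undefined angle).
    """
    a = np.asarray(p_a, dtype=float) - np.asarray(p_vertex, dtype=float)
    b = np.asarray(p_b, dtype=float) - np.asarray(p_vertex, dtype=float)
    na = math.hypot(*a)
    nb = math.hypot(*b)
    if na == 0.0 or nb == 0.0:
        return math.nan
    c = float(np.dot(a, b)) / (na * nb)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@dataclass
class AngleSeries:
    """Named joint-angle channels for one trial, sampled per frame (degrees)."""

    trial_id: str
    movement: str
    fps: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def frame_count(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    def __post_init__(self):
        n = None
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            self.channels[name] = arr
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError(f"channel {name}: length {len(arr)} != {n}")


def compute_angle_channels(
    stream,
    defs: tuple[AngleDefinition, ...] = DEFAULT_ANGLE_DEFINITIONS,
    visibility_min: float = 0.5,
) -> AngleSeries:
    """Evaluate each angle definition on every frame of a keypoint stream.

    A frame contributes NaN to a channel when any of its three landmarks is
    missing or has visibility below ``visibility_min``.
    """
    vocab = set(stream.frames[0].landmarks) if stream.frames else set()
    for d in defs:
        missing = {d.vertex, d.ray_a, d.ray_b} - vocab
        if missing:
            raise KeyError(f"channel {d.channel_name}: landmarks {sorted(missing)} absent from stream")

    channels: dict[str, np.ndarray] = {}
    for d in defs:
        vals = np.full(len(stream.frames), np.nan)
        for i, frame in enumerate(stream.frames):
            pts = []
            ok = True
            for name in (d.ray_a, d.vertex, d.ray_b):
                lm = frame.landmarks.get(name)
                if lm is None or lm.visibility < visibility_min:
                    ok = False
                    break
                pts.append((lm.x, lm.y))
            if ok:
                vals[i] = vector_angle(pts[0], pts[1], pts[2])
        channels[d.channel_name] = vals
    return AngleSeries(
        trial_id=stream.trial_id, movement=stream.movement, fps=stream.fps, channels=channels
    )


def interpolate_gaps(series: AngleSeries, max_gap_frames: int = 3) -> AngleSeries:
    """Linearly fill NaN runs of length <= ``max_gap_frames``.

    Longer runs and leading/trailing gaps are left missing: there is no
    flanking value to anchor them, and inventing one would bias the windowed
    statistics.
    """
    out: dict[str, np.ndarray] = {}
    for name, arr in series.channels.items():
        filled = arr.copy()
        n = len(arr)
        i = 0
        while i < n:
            if np.isnan(arr[i]):
                j = i
                while j < n and np.isnan(arr[j]):
                    j += 1
                run = j - i
                if 0 < i and j < n and run <= max_gap_frames:
                    lo, hi = arr[i - 1], arr[j]
                    for k in range(run):
                        filled[i + k] = lo + (hi - lo) * (k + 1) / (run + 1)
                i = j
            else:
                i += 1
        out[name] = filled
    return AngleSeries(series.trial_id, series.movement, series.fps, out)


# ---------------------------------------------------------------------------
# CSV dialect: frame,time_s,<channel...> with empty cells for missing values


def write_angle_series(series: AngleSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = series.frame_count
    df = pd.DataFrame({"frame": np.arange(n), "time_s": np.arange(n) / series.fps})
    for name in series.channels:
        df[name] = series.channels[name]
    with open(path, "w") as fh:
        fh.write(f"#trial_id={series.trial_id}\n#movement={series.movement}\n#fps={series.fps!r}\n")
        df.to_csv(fh, index=False, na_rep="")
    return path


def read_angle_series(path: str | Path) -> AngleSeries:
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
    df = pd.read_csv(io.StringIO("".join(lines[body:])))
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c not in ("frame", "time_s")}
    return AngleSeries(
        trial_id=meta.get("trial_id", path.stem),
        movement=meta.get("movement", "M1"),
        fps=float(meta.get("fps", 30.0)),
        channels=channels,
    )
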