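"""Pose keypoint stream I/O and validation.

A keypoint stream is one trial's worth of frame-indexed 2-D body landmarks,
as produced by any pose estimator (MediaPipe-class models emit exactly this
shape: per-frame landmark coordinates with a visibility confidence). The
on-disk dialect is a long CSV with header ``frame,time_s,landmark,x,y,visibility``
preceded by ``#key=value`` metadata lines; a JSON schema mirrors it.

Coordinates may be pixels or normalised [0, 1] — downstream joint angles are
invariant to uniform scaling, so no unit is enforced. The y axis increases
downward (image convention).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CORE_LANDMARKS",
    "MOVEMENTS",
    "CLASSIFIED_MOVEMENTS",
    "Landmark",
    "KeypointFrame",
    "KeypointStream",
    "TrialLabel",
    "KeypointParseError",
    "read_keypoint_stream",
    "write_keypoint_stream",
    "validate_stream",
    "read_trial_labels",
    "write_trial_labels",
]

#: Minimum landmark vocabulary: the 10 points needed for the six angle channels.
CORE_LANDMARKS: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_foot_index",
    "right_foot_index",
)

#: The nine chair-based resistance movements.
MOVEMENTS: tuple[str, ...] = tuple(f"M{i}" for i in range(1, 10))

#: Movements with a correct/incorrect classifier; M5 (stand-up) is excluded.
CLASSIFIED_MOVEMENTS: tuple[str, ...] = tuple(m for m in MOVEMENTS if m != "M5")

CONDITIONS = ("modified", "regular")
CORRECTNESS = ("correct", "incorrect")


class KeypointParseError(ValueError):
    """Malformed keypoint or label file; the message names the offending line."""


@dataclass(frozen=True)
class Landmark:
    """One named 2-D image point with detection confidence."""

    name: str
    x: float
    y: float
    visibility: float = 1.0


@dataclass(frozen=True)
class KeypointFrame:
    frame_index: int
    time_s: float
    landmarks: dict[str, Landmark] = field(default_factory=dict)


@dataclass
class KeypointStream:
    """All keypoint frames of a single recorded trial."""

    trial_id: str
    movement: str
    frames: list[KeypointFrame]
    fps: float = 30.0
    condition: str = "modified"
    correctness_label: str | None = None
    subject: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def landmark_array(self, name: str):
        """Return (x, y, visibility) per frame for one landmark as three lists."""
        xs, ys, vs = [], [], []
        for f in self.frames:
            lm = f.landmarks.get(name)
            if lm is None:
                xs.append(math.nan)
                ys.append(math.nan)
                vs.append(0.0)
            else:
                xs.append(lm.x)
                ys.append(lm.y)
                vs.append(lm.visibility)
        return xs, ys, vs


@dataclass(frozen=True)
class TrialLabel:
    trial_id: str
    movement: str
    correctness_label: str | None
    condition: str = "modified"
    subject: str | None = None


# ---------------------------------------------------------------------------
# CSV / JSON dialects


_META_KEYS = ("trial_id", "movement", "fps", "condition", "correctness_label", "subject")
_CSV_HEADER = ["frame", "time_s", "landmark", "x", "y", "visibility"]


def _parse_meta(lines: list[str], path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" not in body:
            raise KeypointParseError(f"{path}: malformed metadata line {ln!r}")
        k, v = body.split("=", 1)
        meta[k.strip()] = v.strip()
    return meta


def read_keypoint_stream(
    path: str | Path,
    fps: float | None = None,
    strict_vocabulary: bool = False,
) -> KeypointStream:
    """Read a keypoint stream from the long-CSV or JSON dialect.

    Frames are returned sorted by ``frame_index`` regardless of row order,
    and ``time_s`` is filled from ``frame_index / fps`` when absent. With
    ``strict_vocabulary=True`` any landmark name outside the core vocabulary
    raises; by default extra landmarks pass through untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _read_json(path, fps, strict_vocabulary)
    return _read_csv(path, fps, strict_vocabulary)


def _check_name(name: str, strict: bool, where: str) -> None:
    if not name or not name.replace("_", "").isalnum():
        raise KeypointParseError(f"{where}: invalid landmark name {name!r}")
    if strict and name not in CORE_LANDMARKS:
        raise KeypointParseError(f"{where}: unknown landmark {name!r} (strict vocabulary)")


def _read_csv(path: Path, fps: float | None, strict: bool) -> KeypointStream:
    meta_lines: list[str] = []
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        data_lines = []
        for raw in fh:
            if raw.startswith("#"):
                meta_lines.append(raw.rstrip("\n"))
            elif raw.strip():
                data_lines.append(raw)
        if not data_lines:
            raise KeypointParseError(f"{path}: empty keypoint file")
        reader = csv.DictReader(data_lines)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_HEADER:
            raise KeypointParseError(
                f"{path}: expected header {','.join(_CSV_HEADER)!r}, got {reader.fieldnames}"
            )
        rows = list(reader)
    if not rows:
        raise KeypointParseError(f"{path}: no data rows")

    meta = _parse_meta(meta_lines, str(path))
    stream_fps = fps if fps is not None else float(meta.get("fps", 30.0))
    if stream_fps <= 0:
        raise KeypointParseError(f"{path}: fps must be positive, got {stream_fps}")

    by_frame: dict[int, dict[str, Landmark]] = {}
    times: dict[int, float] = {}
    for lineno, row in enumerate(rows, start=2 + len(meta_lines)):
        try:
            idx = int(row["frame"])
            name = row["landmark"].strip()
            x = float(row["x"])
            y = float(row["y"])
            vis = float(row["visibility"]) if row["visibility"] not in ("", None) else 1.0
            t = float(row["time_s"]) if row["time_s"] not in ("", None) else idx / stream_fps
        except (KeyError, TypeError, ValueError) as exc:
            raise KeypointParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        if idx < 0:
            raise KeypointParseError(f"{path}: negative frame index at line {lineno}")
        _check_name(name, strict, f"{path}: line {lineno}")
        by_frame.setdefault(idx, {})[name] = Landmark(name, x, y, vis)
        times[idx] = t

    frames = [
        KeypointFrame(frame_index=i, time_s=times[i], landmarks=by_frame[i])
        for i in sorted(by_frame)
    ]
    return KeypointStream(
        trial_id=meta.get("trial_id", path.stem),
        movement=meta.get("movement", "M1"),
        frames=frames,
        fps=stream_fps,
        condition=meta.get("condition", "modified"),
        correctness_label=meta.get("correctness_label") or None,
        subject=meta.get("subject") or None,
    )


def _read_json(path: Path, fps: float | None, strict: bool) -> KeypointStream:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise KeypointParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise KeypointParseError(f"{path}: JSON stream must be an object with a 'frames' key")
    stream_fps = fps if fps is not None else float(doc.get("fps", 30.0))
    frames = []
    for f in doc["frames"]:
        idx = int(f["frame"])
        t = float(f.get("time_s", idx / stream_fps))
        lms = {}
        for name, rec in f["landmarks"].items():
            _check_name(name, strict, f"{path}: frame {idx}")
            lms[name] = Landmark(name, float(rec["x"]), float(rec["y"]), float(rec.get("visibility", 1.0)))
        frames.append(KeypointFrame(idx, t, lms))
    if not frames:
        raise KeypointParseError(f"{path}: stream has no frames")
    frames.sort(key=lambda fr: fr.frame_index)
    return KeypointStream(
        trial_id=doc.get("trial_id", path.stem),
        movement=doc.get("movement", "M1"),
        frames=frames,
        fps=stream_fps,
        condition=doc.get("condition", "modified"),
        correctness_label=doc.get("correctness_label"),
        subject=doc.get("subject"),
    )


def write_keypoint_stream(stream: KeypointStream, path: str | Path) -> Path:
    """Write a stream; ``read_keypoint_stream`` round-trips it field-for-field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        doc = {
            "trial_id": stream.trial_id,
            "movement": stream.movement,
            "fps": stream.fps,
            "condition": stream.condition,
            "correctness_label": stream.correctness_label,
            "subject": stream.subject,
            "frames": [
                {
                    "frame": f.frame_index,
                    "time_s": f.time_s,
                    "landmarks": {
                        n: {"x": lm.x, "y": lm.y, "visibility": lm.visibility}
                        for n, lm in sorted(f.landmarks.items())
                    },
                }
                for f in stream.frames
            ],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        return path

    lines = []
    meta = {
        "trial_id": stream.trial_id,
        "movement": stream.movement,
        "fps": repr(stream.fps),
        "condition": stream.condition,
        "correctness_label": stream.correctness_label or "",
        "subject": stream.subject or "",
    }
    for k in _META_KEYS:
        lines.append(f"#{k}={meta[k]}")
    lines.append(",".join(_CSV_HEADER))
    for f in stream.frames:
        for name in sorted(f.landmarks):
            lm = f.landmarks[name]
            lines.append(
                f"{f.frame_index},{f.time_s!r},{name},{lm.x!r},{lm.y!r},{lm.visibility!r}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Validation


def validate_stream(stream: KeypointStream) -> list[str]:
    """Return diagnostics for every violated invariant (empty list = valid)."""
    diags: list[str] = []
    if stream.fps <= 0:
        diags.append(f"fps: must be > 0, got {stream.fps}")
    if not stream.frames:
        diags.append("frames: stream is empty")
    if stream.movement not in MOVEMENTS:
        diags.append(f"movement: {stream.movement!r} not in M1..M9")
    if stream.correctness_label is not None and stream.correctness_label not in CORRECTNESS:
        diags.append(f"correctness_label: {stream.correctness_label!r} invalid")
    seen: set[int] = set()
    prev_t = -math.inf
    vocab: set[str] | None = None
    for f in stream.frames:
        if f.frame_index in seen:
            diags.append(f"frame {f.frame_index}: duplicate frame index")
        seen.add(f.frame_index)
        if f.time_s <= prev_t:
            diags.append(f"frame {f.frame_index}: time_s not strictly increasing")
        prev_t = f.time_s
        names = set(f.landmarks)
        if vocab is None:
            vocab = names
        elif names != vocab:
            diags.append(f"frame {f.frame_index}: landmark vocabulary differs from first frame")
        for name, lm in f.landmarks.items():
            if not (0.0 <= lm.visibility <= 1.0):
                diags.append(f"frame {f.frame_index}: visibility of {name} = {lm.visibility} outside [0, 1]")
            if not (math.isfinite(lm.x) and math.isfinite(lm.y)):
                diags.append(f"frame {f.frame_index}: non-finite coordinate for {name}")
    return diags


# ---------------------------------------------------------------------------
# Trial labels


def read_trial_labels(path: str | Path) -> list[TrialLabel]:
    """Read labels CSV ``trial_id,movement,correctness,condition[,subject]``."""
    path = Path(path)
    labels = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        required = {"trial_id", "movement", "correctness", "condition"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise KeypointParseError(f"{path}: labels CSV needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            movement = row["movement"].strip()
            if movement not in MOVEMENTS:
                raise KeypointParseError(f"{path}: line {lineno}: bad movement {movement!r}")
            corr = row["correctness"].strip() or None
            if corr is not None and corr not in CORRECTNESS:
                raise KeypointParseError(f"{path}: line {lineno}: bad correctness {corr!r}")
            labels.append(
                TrialLabel(
                    trial_id=row["trial_id"].strip(),
                    movement=movement,
                    correctness_label=corr,
                    condition=row["condition"].strip() or "modified",
                    subject=(row.get("subject") or "").strip() or None,
                )
            )
    return labels


def write_trial_labels(labels: Iterable[TrialLabel], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["trial_id,movement,correctness,condition,subject"]
    for lab in labels:
        lines.append(
            f"{lab.trial_id},{lab.movement},{lab.correctness_label or ''},{lab.condition},{lab.subject or ''}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
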