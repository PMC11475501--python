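"""Sliding-window feature extraction from joint-angle channels.

Each angle channel is cut into windows of 30 samples with a step of 15
(50% overlap), and every window yields ten statistics: five time-domain
(Mean, Min, Max, Std, Median) and five computed on the Welch power spectrum
within a 1–20 Hz band (Power_Mean, Power_Max, Power_Min, Power_Std,
Power_Median). With all six channels included this gives the 60-column
feature table used by the per-movement classifiers.

Feature columns are named ``<stat><suffix>`` where the suffix encodes the
channel position: the first channel gets no suffix, the second ``.1`` and so
on (``Mean``, ``Mean.1`` … ``Power_Median.5``).

Notes on conventions the windowed statistics depend on:

* Std uses the population denominator (ddof=0), applied uniformly to time
  and power statistics.
* Welch PSD: Hann taper, constant detrend, segment length = window size
  (a 30-sample window is too short to subdivide further), one-sided.
* At 30 fps the Nyquist frequency is 15 Hz, so the nominal 1–20 Hz band is
  clipped to [1, fs/2]; the clipping is reported as a diagnostic.
* Windows that overlap any missing (NaN) angle are excluded, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .angles import CHANNEL_ORDER, AngleSeries
from .keypoints import TrialLabel

__all__ = [
    "WindowSpec",
    "Window",
    "FeatureTable",
    "TIME_STATS",
    "POWER_STATS",
    "STAT_NAMES",
    "feature_columns",
    "channel_suffix",
    "make_windows",
    "time_stats",
    "welch_power_stats",
    "build_feature_table",
]

log = logging.getLogger(__name__)

TIME_STATS = ("Mean", "Min", "Max", "Std", "Median")
POWER_STATS = ("Power_Mean", "Power_Max", "Power_Min", "Power_Std", "Power_Median")
STAT_NAMES = TIME_STATS + POWER_STATS

META_COLUMNS = ("trial_id", "movement", "label", "window_index")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and sampling rate."""

    size: int = 30
    step: int = 15
    fs: float = 30.0
    band: tuple[float, float] = (1.0, 20.0)

    def __post_init__(self):
        if not (0 < self.step <= self.size):
            raise ValueError(f"require 0 < step <= size, got step={self.step}, size={self.size}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def n_windows(self, n_samples: int) -> int:
        """Number of full windows in a series of ``n_samples`` points."""
        if n_samples < self.size:
            return 0
        return (n_samples - self.size) // self.step + 1


@dataclass(frozen=True)
class Window:
    index: int
    start: int
    segments: dict[str, np.ndarray]


def channel_suffix(position: int) -> str:
    """Figure-style column suffix: '' for the first channel, '.1', '.2', ..."""
    return "" if position == 0 else f".{position}"


def feature_columns(channels: Sequence[str] = CHANNEL_ORDER) -> list[str]:
    """Ordered feature column names for a channel set (10 per channel)."""
    cols = []
    for pos, _ in enumerate(channels):
        cols.extend(stat + channel_suffix(pos) for stat in STAT_NAMES)
    return cols


def channel_feature_columns(channel: str, channels: Sequence[str] = CHANNEL_ORDER) -> list[str]:
    """The 10 feature column names belonging to one channel."""
    pos = list(channels).index(channel)
    return [stat + channel_suffix(pos) for stat in STAT_NAMES]


def make_windows(
    series: AngleSeries,
    spec: WindowSpec = WindowSpec(),
    channels: Sequence[str] | None = None,
) -> tuple[list[Window], int]:
    """Cut a series into full windows; drop windows that touch a NaN.

    Returns ``(clean_windows, n_excluded)``. Window i covers samples
    ``[i*step, i*step + size)``; only complete windows are emitted, so the
    count is ``floor((N - size) / step) + 1`` for N >= size and 0 otherwise.
    """
    names = list(channels) if channels is not None else list(series.channels)
    n = series.frame_count
    total = spec.n_windows(n)
    if total == 0:
        log.warning("series %s: %d frames shorter than one %d-sample window", series.trial_id, n, spec.size)
        return [], 0
    windows: list[Window] = []
    excluded = 0
    for i in range(total):
        start = i * spec.step
        segs = {c: series.channels[c][start : start + spec.size] for c in names}
        if any(np.isnan(seg).any() for seg in segs.values()):
            excluded += 1
            continue
        windows.append(Window(index=i, start=start, segments=segs))
    return windows, excluded


def time_stats(segment: np.ndarray) -> dict[str, float]:
    """Five time-domain statistics of one window segment."""
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("time_stats: empty segment")
    return {
        "Mean": float(seg.mean()),
        "Min": float(seg.min()),
        "Max": float(seg.max()),
        "Std": float(seg.std(ddof=0)),
        "Median": float(np.median(seg)),
    }


def in_band_frequencies(spec: WindowSpec) -> np.ndarray:
    """PSD bin frequencies falling in the (Nyquist-clipped) analysis band."""
    f, _ = signal.welch(np.zeros(spec.size), fs=spec.fs, nperseg=spec.size, detrend="constant")
    lo, hi = effective_band(spec)
    return f[(f >= lo) & (f <= hi)]


def effective_band(spec: WindowSpec) -> tuple[float, float]:
    lo, hi = spec.band
    nyq = spec.fs / 2.0
    if hi > nyq:
        log.debug("band upper edge %.3g Hz clipped to Nyquist %.3g Hz", hi, nyq)
        hi = nyq
    if lo >= hi:
        raise ValueError(f"empty analysis band after Nyquist clipping: [{lo}, {hi}] Hz")
    return lo, hi


def welch_power_stats(segment: np.ndarray, spec: WindowSpec = WindowSpec()) -> dict[str, float]:
    """Five statistics of the in-band Welch power spectrum of one segment."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 8:
        raise ValueError(f"welch_power_stats: segment of {seg.size} samples is too short")
    nperseg = min(seg.size, spec.size)
    f, pxx = signal.welch(
        seg, fs=spec.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend="constant"
    )
    lo, hi = effective_band(spec)
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValueError(f"no PSD bins in band [{lo}, {hi}] Hz at fs={spec.fs}")
    p = pxx[mask]
    return {
        "Power_Mean": float(p.mean()),
        "Power_Max": float(p.max()),
        "Power_Min": float(p.min()),
        "Power_Std": float(p.std(ddof=0)),
        "Power_Median": float(np.median(p)),
    }


@dataclass
class FeatureTable:
    """Windowed feature matrix with trial metadata.

    ``frame`` holds one row per retained window: the four metadata columns
    (trial_id, movement, label, window_index) followed by 10 feature columns
    per channel in ``channel_set`` order.
    """

    frame: pd.DataFrame
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    channel_set: tuple[str, ...] = CHANNEL_ORDER

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def labels01(self) -> np.ndarray:
        """Class labels encoded 0=incorrect, 1=correct."""
        return (self.frame["label"] == "correct").to_numpy(dtype=int)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, window_spec: WindowSpec | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        n_feat = len([c for c in df.columns if c not in META_COLUMNS])
        channels = CHANNEL_ORDER[: n_feat // len(STAT_NAMES)]
        return cls(frame=df, window_spec=window_spec or WindowSpec(), channel_set=tuple(channels))


def _row_features(window: Window, order: Sequence[str], spec: WindowSpec) -> dict[str, float]:
    feats: dict[str, float] = {}
    for pos, channel in enumerate(order):
        suf = channel_suffix(pos)
        seg = window.segments[channel]
        for k, v in time_stats(seg).items():
            feats[k + suf] = v
        for k, v in welch_power_stats(seg, spec).items():
            feats[k + suf] = v
    return feats


def build_feature_table(
    series_list: Iterable[AngleSeries],
    labels: Iterable[TrialLabel],
    spec: WindowSpec = WindowSpec(),
    channels: Sequence[str] = CHANNEL_ORDER,
) -> FeatureTable:
    """Window every labelled series and assemble the feature matrix.

    Every retained window inherits its trial's correctness label. Trials
    without a label raise; windows touching missing angles are dropped.
    """
    label_map = {lab.trial_id: lab for lab in labels}
    rows: list[dict] = []
    for series in series_list:
        lab = label_map.get(series.trial_id)
        if lab is None:
            raise KeyError(f"trial {series.trial_id!r} has no entry in the label table")
        windows, excluded = make_windows(series, spec, channels)
        if excluded:
            log.info("trial %s: %d windows excluded for missing values", series.trial_id, excluded)
        for w in windows:
            row: dict = {
                "trial_id": series.trial_id,
                "movement": series.movement,
                "label": lab.correctness_label,
                "window_index": w.index,
            }
            row.update(_row_features(w, channels, spec))
            rows.append(row)
    cols = list(META_COLUMNS) + feature_columns(channels)
    df = pd.DataFrame(rows, columns=cols)
    return FeatureTable(frame=df, window_spec=spec, channel_set=tuple(channels))
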