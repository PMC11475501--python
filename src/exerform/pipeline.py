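"""End-to-end helpers tying keypoints → angles → features → evaluation."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .angles import DEFAULT_ANGLE_DEFINITIONS, compute_angle_channels, interpolate_gaps
from .classify import (
    CHANNEL_SELECTION,
    ModelConfig,
    MovementCorrectnessModel,
    MovementCorrectnessResults,
    mean_accuracy,
)
from .features import FeatureTable, WindowSpec, build_feature_table
from .keypoints import KeypointStream, TrialLabel

__all__ = ["extract_features", "evaluate_movements", "summarize_accuracy"]

log = logging.getLogger(__name__)


def extract_features(
    streams: Iterable[KeypointStream],
    labels: Sequence[TrialLabel],
    spec: WindowSpec = WindowSpec(),
    visibility_min: float = 0.5,
    max_gap_frames: int = 3,
) -> FeatureTable:
    """Angle extraction, gap interpolation and windowed features in one pass."""
    series_list = []
    for stream in streams:
        series = compute_angle_channels(stream, DEFAULT_ANGLE_DEFINITIONS, visibility_min)
        series_list.append(interpolate_gaps(series, max_gap_frames))
    return build_feature_table(series_list, labels, spec)


def evaluate_movements(
    table: FeatureTable,
    config: ModelConfig = ModelConfig(),
    movements: Sequence[str] | None = None,
) -> dict[str, MovementCorrectnessResults]:
    """Fit and LOOCV-evaluate one correctness model per movement.

    Movements with a single class present are skipped with a warning rather
    than failing the whole run.
    """
    present = list(dict.fromkeys(table.frame["movement"]))
    wanted = [m for m in (movements or present) if m in CHANNEL_SELECTION]
    results: dict[str, MovementCorrectnessResults] = {}
    for movement in wanted:
        if movement not in present:
            continue
        try:
            results[movement] = MovementCorrectnessModel(table, movement, config).fit()
        except ValueError as exc:
            log.warning("movement %s skipped: %s", movement, exc)
    return results


def summarize_accuracy(results: dict[str, MovementCorrectnessResults]) -> float:
    """Unweighted mean accuracy over movements, in percent."""
    return mean_accuracy([r.report for r in results.values()])
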