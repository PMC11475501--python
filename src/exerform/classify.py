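"""Per-movement correctness classification.

For each movement a dedicated binary classifier decides whether a feature
window comes from a correctly or incorrectly executed repetition. The
pipeline per movement is:

1. **Channel screening** — keep only the feature columns of the angle
   channel(s) known to discriminate that movement (one channel for most
   movements, two for M8, nothing for M5 which has no classifier).
2. **Standardisation + PCA** — features are z-scored and projected onto the
   smallest number of principal components explaining the target variance
   fraction (default 0.95, minimum 2 components).
3. **SVM** — a radial-basis-kernel support vector machine (C = 1.0, kernel
   width 1 / (n_features × feature variance), i.e. scikit-learn's "scale").
4. **LOOCV** — leave-one-out cross-validation: every window is predicted by
   a pipeline fitted on all other windows, so standardisation and PCA are
   re-fitted inside each training fold and never see the held-out row.

Class encoding is fixed: 0 = incorrect, 1 = correct.

The statsmodels-style entry point is :class:`MovementCorrectnessModel`,
whose ``fit()`` returns a :class:`MovementCorrectnessResults` carrying the
per-class precision/recall/F1/support, the overall accuracy and a
``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import precision_recall_fscore_support
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import META_COLUMNS, FeatureTable, channel_feature_columns

__all__ = [
    "CHANNEL_SELECTION",
    "ModelConfig",
    "ProjectionModel",
    "ClassificationReport",
    "MovementCorrectnessModel",
    "MovementCorrectnessResults",
    "select_channels",
    "fit_projection",
    "loocv_evaluate",
    "mean_accuracy",
    "reconstruct_accuracy",
    "render_report",
    "parse_report",
]

log = logging.getLogger(__name__)

#: Discriminative angle channel(s) per movement. M5 (stand-up) has none.
CHANNEL_SELECTION: dict[str, tuple[str, ...]] = {
    "M1": ("left_knee_ankle",),
    "M2": ("left_hip_knee",),
    "M3": ("left_shoulder_hip",),
    "M4": ("left_knee_ankle",),
    "M6": ("left_shoulder_hip",),
    "M7": ("left_knee_ankle",),
    "M8": ("left_shoulder_hip", "right_shoulder_hip"),
    "M9": ("left_shoulder_hip",),
}


@dataclass(frozen=True)
class ModelConfig:
    """Classifier hyper-parameters and evaluation mode."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    variance_target: float = 0.95
    min_components: int = 2
    cv_mode: str = "window"  # "window": LOO over rows; "trial": leave-one-trial-out
    seed: int = 0


class UnsupportedMovementError(ValueError):
    pass


def select_channels(table: FeatureTable, movement: str) -> FeatureTable:
    """Restrict a feature table to the selected channel(s) of one movement."""
    if movement not in CHANNEL_SELECTION:
        raise UnsupportedMovementError(
            f"movement {movement!r} has no channel selection (M5 is excluded by design)"
        )
    cols: list[str] = []
    for channel in CHANNEL_SELECTION[movement]:
        cols.extend(channel_feature_columns(channel, table.channel_set))
    sub = table.frame[table.frame["movement"] == movement]
    frame = sub[list(META_COLUMNS) + cols].reset_index(drop=True)
    return FeatureTable(frame=frame, window_spec=table.window_spec, channel_set=CHANNEL_SELECTION[movement])


# ---------------------------------------------------------------------------
# Standardisation + PCA


@dataclass
class ProjectionModel:
    """Fitted z-scoring + PCA projection."""

    scaler: StandardScaler
    pca: PCA
    kept_features: list[str]
    n_components: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        return self.pca.transform(Z)[:, : self.n_components]


def fit_projection(
    X: np.ndarray | FeatureTable,
    variance_target: float = 0.95,
    min_components: int = 2,
    feature_names: Sequence[str] | None = None,
) -> ProjectionModel:
    """Fit standardisation and PCA, retaining enough components for the target.

    Zero-variance features cannot be z-scored and are dropped with a logged
    diagnostic. The component count is the smallest reaching
    ``variance_target`` cumulative explained variance, but never fewer than
    ``min_components`` (capped by the available rank).
    """
    if isinstance(X, FeatureTable):
        feature_names = X.feature_names
        X = X.features()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"fit_projection needs a 2-D matrix with >= 2 rows, got {X.shape}")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]

    variances = X.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        log.warning("dropping zero-variance features: %s", dropped)
    if not keep.any():
        raise ValueError("all features have zero variance")
    Xk = X[:, keep]
    kept = [n for n, k in zip(names, keep) if k]

    scaler = StandardScaler().fit(Xk)
    pca = PCA(svd_solver="full").fit(scaler.transform(Xk))
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(max(k, min_components), len(evr))
    return ProjectionModel(scaler=scaler, pca=pca, kept_features=kept,
                           n_components=k, explained_variance_ratio=evr)


# ---------------------------------------------------------------------------
# Classification report


@dataclass
class ClassificationReport:
    """Per-class and aggregate LOOCV metrics for one movement's classifier."""

    movement: str
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    accuracy: float

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    @property
    def macro_avg(self) -> dict[str, float]:
        return {
            "precision": float(np.mean([self.precision[c] for c in (0, 1)])),
            "recall": float(np.mean([self.recall[c] for c in (0, 1)])),
            "f1": float(np.mean([self.f1[c] for c in (0, 1)])),
        }

    @property
    def weighted_avg(self) -> dict[str, float]:
        n = self.total_support
        w = {c: self.support[c] / n for c in (0, 1)}
        return {
            "precision": sum(self.precision[c] * w[c] for c in (0, 1)),
            "recall": sum(self.recall[c] * w[c] for c in (0, 1)),
            "f1": sum(self.f1[c] * w[c] for c in (0, 1)),
        }

    @classmethod
    def from_predictions(cls, movement: str, y_true: np.ndarray, y_pred: np.ndarray) -> "ClassificationReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        prec, rec, f1, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1], zero_division=0
        )
        return cls(
            movement=movement,
            precision={0: float(prec[0]), 1: float(prec[1])},
            recall={0: float(rec[0]), 1: float(rec[1])},
            f1={0: float(f1[0]), 1: float(f1[1])},
            support={0: int(sup[0]), 1: int(sup[1])},
            accuracy=float((y_true == y_pred).mean()),
        )

    def to_dict(self) -> dict:
        return {
            "movement": self.movement,
            "accuracy": self.accuracy,
            "classes": {
                str(c): {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in (0, 1)
            },
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "total_support": self.total_support,
        }


# ---------------------------------------------------------------------------
# LOOCV


def loocv_evaluate(
    table: FeatureTable,
    movement: str,
    config: ModelConfig = ModelConfig(),
    fold_hook: Callable[[int, ProjectionModel, SVC], None] | None = None,
) -> ClassificationReport:
    """Leave-one-out evaluation with fold-internal preprocessing.

    In "window" mode every feature row is held out once; in "trial" mode all
    windows of one trial are held out together (overlapping windows of a
    trial are temporally correlated, so trial-level folds are the stricter
    evaluation). ``fold_hook`` receives the fitted fold pipeline and exists
    for instrumentation (e.g. leakage checks).
    """
    sub = select_channels(table, movement) if set(CHANNEL_SELECTION.get(movement, ())) != set(table.channel_set) else table
    X = sub.features()
    y = sub.labels01()
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(
            f"movement {movement}: LOOCV needs both classes with >= 2 rows, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )

    if config.cv_mode == "trial":
        groups = sub.frame["trial_id"].to_numpy()
        fold_ids = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    elif config.cv_mode == "window":
        fold_ids = [np.array([i]) for i in range(n)]
    else:
        raise ValueError(f"unknown cv_mode {config.cv_mode!r}")

    y_pred = np.empty(n, dtype=int)
    names = sub.feature_names
    for k, test_idx in enumerate(fold_ids):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        proj = fit_projection(
            X[train_mask], config.variance_target, config.min_components, feature_names=names
        )
        keep_cols = [names.index(f) for f in proj.kept_features]
        clf = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma, random_state=config.seed)
        clf.fit(proj.transform(X[train_mask][:, keep_cols]), y[train_mask])
        y_pred[test_idx] = clf.predict(proj.transform(X[test_idx][:, keep_cols]))
        if fold_hook is not None:
            fold_hook(k, proj, clf)
    return ClassificationReport.from_predictions(movement, y, y_pred)


def mean_accuracy(reports: Sequence[ClassificationReport] | Sequence[float]) -> float:
    """Unweighted mean of per-movement accuracies, in percent."""
    if len(reports) == 0:
        raise ValueError("mean_accuracy: no reports")
    accs = [r.accuracy if isinstance(r, ClassificationReport) else float(r) for r in reports]
    accs = [a / 100.0 if a > 1.0 else a for a in accs]  # accept fractions or percents
    return 100.0 * float(np.mean(accs))


def reconstruct_accuracy(recalls: dict[int, float], supports: dict[int, int]) -> float:
    """Overall accuracy (percent) from per-class recalls and supports.

    Per-class recall times support counts the correctly predicted rows of
    that class, so their sum over classes divided by the total support is
    the overall accuracy. Useful for checking a printed report's internal
    consistency at its printed precision.
    """
    total = sum(supports.values())
    correct = sum(recalls[c] * supports[c] for c in supports)
    return 100.0 * correct / total


# ---------------------------------------------------------------------------
# Report rendering (fixed-width text table)


def render_report(report: ClassificationReport) -> str:
    """Fixed-width text block: per-class rows, accuracy, macro/weighted avgs.

    The header states the overall accuracy as a percent with four decimals;
    table cells are rounded to two decimals.
    """
    num = report.movement.lstrip("M") or report.movement
    lines = [f"Average Accuracy {num}: {100.0 * report.accuracy:.4f}%"]
    lines.append(f"{'':<14}{'Precision':>10}{'Recall':>10}{'F1-score':>10}{'Support':>10}")
    for c in (0, 1):
        lines.append(
            f"{c:<14}{report.precision[c]:>10.2f}{report.recall[c]:>10.2f}"
            f"{report.f1[c]:>10.2f}{report.support[c]:>10d}"
        )
    lines.append(f"{'Accuracy':<14}{'':>10}{'':>10}{report.accuracy:>10.2f}{report.total_support:>10d}")
    for name, avg in (("Macro Avg", report.macro_avg), ("Weighted Avg", report.weighted_avg)):
        lines.append(
            f"{name:<14}{avg['precision']:>10.2f}{avg['recall']:>10.2f}"
            f"{avg['f1']:>10.2f}{report.total_support:>10d}"
        )
    return "\n".join(lines)


def parse_report(text: str) -> dict:
    """Parse a rendered report back into its rounded numbers (for round trips)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    m = re.match(r"Average Accuracy (\S+): ([\d.]+)%", lines[0])
    if not m:
        raise ValueError("not a rendered report")
    out: dict = {"movement": "M" + m.group(1), "accuracy_pct": float(m.group(2)), "classes": {}}
    for ln in lines[2:4]:
        parts = ln.split()
        out["classes"][int(parts[0])] = {
            "precision": float(parts[1]),
            "recall": float(parts[2]),
            "f1": float(parts[3]),
            "support": int(parts[4]),
        }
    acc_parts = lines[4].split()
    out["accuracy"] = float(acc_parts[1])
    out["total_support"] = int(acc_parts[2])
    for key, ln in (("macro_avg", lines[5]), ("weighted_avg", lines[6])):
        parts = ln.split()
        out[key] = {"precision": float(parts[-4]), "recall": float(parts[-3]), "f1": float(parts[-2])}
    return out


# ---------------------------------------------------------------------------
# Model / Results objects


class MovementCorrectnessModel:
    """Binary correct/incorrect model for one movement's feature windows.

    Parameters
    ----------
    table : FeatureTable
        Feature windows (any movements; rows are filtered to ``movement``).
    movement : str
        Movement id in M1–M9 except M5.
    config : ModelConfig, optional
        Classifier hyper-parameters and the cross-validation mode.
    """

    def __init__(self, table: FeatureTable, movement: str, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.movement = movement
        self.table = select_channels(table, movement)
        if self.table.n_rows == 0:
            raise ValueError(f"no feature rows for movement {movement}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, movement: str, config: ModelConfig | None = None):
        return cls(FeatureTable(frame=frame), movement, config)

    def fit(self) -> "MovementCorrectnessResults":
        """Run LOOCV and return the evaluation results."""
        report = loocv_evaluate(self.table, self.movement, self.config)
        proj = fit_projection(
            self.table, self.config.variance_target, self.config.min_components,
        )
        return MovementCorrectnessResults(model=self, report=report, projection=proj)


@dataclass
class MovementCorrectnessResults:
    """LOOCV evaluation of one movement's classifier."""

    model: MovementCorrectnessModel
    report: ClassificationReport
    projection: ProjectionModel

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def summary(self) -> str:
        head = (
            f"Movement correctness model — {self.report.movement}\n"
            f"rows: {self.model.table.n_rows}; channels: {', '.join(self.model.table.channel_set)}; "
            f"cv: leave-one-{self.model.config.cv_mode}-out; "
            f"PCA components: {self.projection.n_components} "
            f"({100 * self.projection.explained_variance_ratio[: self.projection.n_components].sum():.1f}% var)\n"
        )
        return head + render_report(self.report)

    def to_json(self) -> str:
        doc = self.report.to_dict()
        doc["config"] = asdict(self.model.config)
        doc["n_components"] = self.projection.n_components
        return json.dumps(doc, indent=1)
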