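"""Channel screening, PCA projection, LOOCV evaluation and reporting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from exerform.classify import (
    CHANNEL_SELECTION,
    ClassificationReport,
    ModelConfig,
    MovementCorrectnessModel,
    UnsupportedMovementError,
    fit_projection,
    loocv_evaluate,
    mean_accuracy,
    parse_report,
    reconstruct_accuracy,
    render_report,
    select_channels,
)
from exerform.features import feature_columns
from exerform.angles import CHANNEL_ORDER
from exerform.keypoints import TrialLabel
from exerform.features import build_feature_table
from test_features import six_channel_series

from conftest import toy_feature_table


def full_table(rng, movements=("M2", "M8")):
    series, labels = [], []
    for m in movements:
        for k, corr in enumerate(["correct", "incorrect"]):
            tid = f"{m}-{k}"
            series.append(six_channel_series(60, trial_id=tid, movement=m, rng=rng))
            labels.append(TrialLabel(tid, m, corr))
    return build_feature_table(series, labels)


def test_select_channels_m2_keeps_10_hip_knee_columns(rng):
    table = full_table(rng)
    sub = select_channels(table, "M2")
    assert len(sub.feature_names) == 10
    assert all(c.endswith(".1") for c in sub.feature_names)  # left_hip_knee position


def test_select_channels_m8_keeps_20_shoulder_hip_columns(rng):
    from exerform.features import STAT_NAMES, channel_suffix

    sub = select_channels(full_table(rng), "M8")
    expected = [s + channel_suffix(0) for s in STAT_NAMES] + [s + channel_suffix(3) for s in STAT_NAMES]
    assert sub.feature_names == expected  # left (no suffix) + right shoulder-hip (.3)


def test_m5_has_no_classifier(rng):
    with pytest.raises(UnsupportedMovementError):
        select_channels(full_table(rng), "M5")


def test_selection_map_covers_all_movements_but_m5():
    assert set(CHANNEL_SELECTION) == {"M1", "M2", "M3", "M4", "M6", "M7", "M8", "M9"}
    assert CHANNEL_SELECTION["M8"] == ("left_shoulder_hip", "right_shoulder_hip")


# ---------------------------------------------------------------------------
# Projection


def test_collinear_data_loads_on_first_component(rng):
    t = rng.uniform(-1, 1, 50)
    X = np.outer(t, [1.0, 2.0, -0.5])
    proj = fit_projection(X, variance_target=0.95)
    assert proj.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
    assert proj.n_components == 2  # floor of two components even when one suffices


def test_isotropic_gaussian_has_equal_ratios(rng):
    X = np.random.default_rng(99).normal(size=(4000, 4))
    proj = fit_projection(X)
    assert np.allclose(proj.explained_variance_ratio, 0.25, atol=0.1)


def test_full_reconstruction_is_identity(rng):
    X = rng.normal(size=(30, 6))
    proj = fit_projection(X, variance_target=1.0)
    Z = proj.scaler.transform(X)
    recon = proj.pca.inverse_transform(proj.pca.transform(Z))
    np.testing.assert_allclose(recon, Z, atol=1e-8)


def test_zero_variance_feature_dropped(rng, caplog):
    X = rng.normal(size=(20, 3))
    X[:, 1] = 7.0
    proj = fit_projection(X, feature_names=["a", "b", "c"])
    assert proj.kept_features == ["a", "c"]


def test_explained_variance_ratios_monotone_and_bounded(rng):
    proj = fit_projection(rng.normal(size=(40, 8)) * np.arange(1, 9))
    evr = proj.explained_variance_ratio
    assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# LOOCV


def separable_table(n=40, gap=20.0, seed=0, movement="M1"):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 3)) + gap * y[:, None]
    return toy_feature_table(X, y, movement=movement)


def test_separable_clusters_reach_perfect_accuracy():
    report = loocv_evaluate(separable_table(40), "M1")
    assert report.accuracy == 1.0
    assert report.support == {0: 20, 1: 20}


def test_permuted_labels_near_chance():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(60, 4))
    y = rng.permutation([0, 1] * 30)
    report = loocv_evaluate(toy_feature_table(X, y), "M1")
    assert abs(report.accuracy - 0.5) < 0.15


def test_single_class_input_is_error():
    table = toy_feature_table(np.random.default_rng(0).normal(size=(10, 3)), np.ones(10, dtype=int))
    with pytest.raises(ValueError, match="both classes"):
        loocv_evaluate(table, "M1")


def test_small_table_matches_sklearn_loocv_oracle():
    """Dual route: manual fold loop vs sklearn cross_val_predict pipeline."""
    rng = np.random.default_rng(5)
    n = 12
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 4)) + 1.5 * y[:, None]
    table = toy_feature_table(X, y)
    cfg = ModelConfig(variance_target=1e-9, min_components=2)  # always exactly 2 components
    report = loocv_evaluate(table, "M1", cfg)

    pipe = make_pipeline(StandardScaler(), PCA(n_components=2, svd_solver="full"), SVC(C=1.0, gamma="scale"))
    y_hat = cross_val_predict(pipe, table.features(), y, cv=LeaveOneOut())
    oracle = ClassificationReport.from_predictions("M1", y, y_hat)
    assert report.accuracy == oracle.accuracy
    assert report.precision == oracle.precision and report.recall == oracle.recall
    assert report.support == oracle.support


def test_training_folds_never_see_test_row():
    """Leakage check: fold parameters are identical after corrupting one
    held-out row's features (window cv: fold k holds out row k)."""
    table = separable_table(16, seed=3)
    means = {}

    def hook(k, proj, clf):
        means[k] = proj.scaler.mean_.copy()

    loocv_evaluate(table, "M1", fold_hook=hook)
    corrupted = table.frame.copy()
    feat_cols = table.feature_names
    corrupted.loc[7, feat_cols] = 1e6  # absurd test-row values
    means2 = {}

    def hook2(k, proj, clf):
        means2[k] = proj.scaler.mean_.copy()

    from exerform.features import FeatureTable

    loocv_evaluate(FeatureTable(corrupted, table.window_spec, table.channel_set), "M1", fold_hook=hook2)
    np.testing.assert_array_equal(means[7], means2[7])


def test_trial_level_folds_hold_out_whole_trials():
    rng = np.random.default_rng(8)
    n = 24
    y = (np.arange(n) // 6) % 2
    X = rng.normal(size=(n, 3)) + 10.0 * y[:, None]
    trials = [f"tr{i // 6}" for i in range(n)]
    table = toy_feature_table(X, y, trial_ids=trials)
    report = loocv_evaluate(table, "M1", ModelConfig(cv_mode="trial"))
    assert report.total_support == n and report.accuracy == 1.0


# ---------------------------------------------------------------------------
# Aggregation & rendering


def test_mean_accuracy_simple_cases():
    assert mean_accuracy([0.9, 0.9, 0.9]) == pytest.approx(90.0)
    assert mean_accuracy([1.0, 0.0]) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        mean_accuracy([])


def test_reconstruct_accuracy_weighted_recall():
    # equal supports: plain mean of recalls
    assert reconstruct_accuracy({0: 0.8, 1: 0.6}, {0: 50, 1: 50}) == pytest.approx(70.0)


def sample_report():
    y_true = np.array([0] * 10 + [1] * 30)
    y_pred = y_true.copy()
    y_pred[:2] = 1  # two class-0 mistakes
    return ClassificationReport.from_predictions("M1", y_true, y_pred)


def test_report_self_consistency():
    r = sample_report()
    assert r.total_support == 40
    assert r.accuracy == pytest.approx((8 + 30) / 40)
    assert r.recall[0] == pytest.approx(8 / 10)
    assert r.macro_avg["f1"] == pytest.approx(0.5 * (r.f1[0] + r.f1[1]))


def test_render_parse_round_trip():
    r = sample_report()
    parsed = parse_report(render_report(r))
    assert parsed["movement"] == "M1"
    assert parsed["accuracy_pct"] == pytest.approx(100 * r.accuracy, abs=5e-5)
    for c in (0, 1):
        assert parsed["classes"][c]["precision"] == pytest.approx(r.precision[c], abs=5e-3)
        assert parsed["classes"][c]["support"] == r.support[c]
    assert parsed["macro_avg"]["f1"] == pytest.approx(r.macro_avg["f1"], abs=5e-3)


def test_equal_supports_make_macro_equal_weighted():
    y_true = np.array([0] * 20 + [1] * 20)
    y_pred = np.concatenate([np.ones(2), np.zeros(18), np.ones(18), np.zeros(2)]).astype(int)
    r = ClassificationReport.from_predictions("M3", y_true, y_pred)
    for k in ("precision", "recall", "f1"):
        assert r.macro_avg[k] == pytest.approx(r.weighted_avg[k])


def test_render_header_format():
    text = render_report(sample_report())
    assert text.startswith("Average Accuracy 1: 95.0000%")


# ---------------------------------------------------------------------------
# Model / Results objects


def test_model_results_summary_and_json():
    table = separable_table(30, movement="M4")
    res = MovementCorrectnessModel(table, "M4").fit()
    assert res.accuracy == 1.0
    text = res.summary()
    assert "M4" in text and "Average Accuracy 4" in text
    import json

    doc = json.loads(res.to_json())
    assert doc["accuracy"] == 1.0 and doc["classes"]["1"]["support"] == 15


def test_accuracy_monotone_in_class_separation():
    """Effect-size dial: wider amplitude gap, higher mean LOOCV accuracy."""
    gaps = [0.0, 1.0, 4.0]
    means = []
    for gap in gaps:
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.arange(24) % 2
            X = rng.normal(size=(24, 3)) + gap * y[:, None]
            accs.append(loocv_evaluate(toy_feature_table(X, y), "M1").accuracy)
        means.append(np.mean(accs))
    assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
    assert means[2] > means[0]
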