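"""Quaternion rotation, RMS stability scoring and paired condition comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.spatial.transform import Rotation

from exerform.imu import (
    ChairStabilityModel,
    IMUStream,
    PairingError,
    StabilityResult,
    compare_conditions,
    horizontal_magnitude,
    mask_active,
    quat_conjugate,
    quat_multiply,
    read_imu_csv,
    read_segments_csv,
    rms,
    rotate_to_earth,
    rotate_to_sensor,
    stability_score,
    write_imu_csv,
    write_segments_csv,
)


def random_unit_quat(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def test_identity_quaternion_is_identity():
    a = np.array([0.3, -0.1, 1.0])
    np.testing.assert_allclose(rotate_to_earth(a, [1, 0, 0, 0]), a, atol=1e-15)


def test_90_degree_rotation_about_z():
    half = np.sqrt(0.5)
    q = np.array([half, 0, 0, half])  # 90 deg about earth Z, Hamilton scalar-first
    np.testing.assert_allclose(rotate_to_earth([1.0, 0.0, 0.0], q), [0.0, 1.0, 0.0], atol=1e-12)


@given(seed=st.integers(0, 1000))
def test_rotation_matches_matrix_oracle_and_preserves_norm(seed):
    rng = np.random.default_rng(seed)
    q = random_unit_quat(rng)
    a = rng.normal(size=3) * 5
    got = rotate_to_earth(a, q)
    oracle = Rotation.from_quat(q, scalar_first=True).apply(a)
    np.testing.assert_allclose(got, oracle, atol=1e-9)
    assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(a), abs=1e-9)


@given(seed=st.integers(0, 1000))
def test_conjugate_round_trip_is_identity(seed):
    rng = np.random.default_rng(seed)
    q = random_unit_quat(rng)
    a = rng.normal(size=3)
    np.testing.assert_allclose(rotate_to_earth(rotate_to_sensor(a, q), q), a, atol=1e-9)


def test_vectorized_rotation_matches_per_sample():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(50, 3))
    Q = np.stack([random_unit_quat(rng) for _ in range(50)])
    got = rotate_to_earth(A, Q)
    want = np.stack([Rotation.from_quat(q, scalar_first=True).apply(a) for a, q in zip(A, Q)])
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_zero_quaternion_rejected():
    with pytest.raises(ValueError, match="zero quaternion"):
        rotate_to_earth([1, 0, 0], [0, 0, 0, 0])


def test_hamilton_product_non_commutative_unit_norm():
    p = np.array([np.cos(0.3), np.sin(0.3), 0, 0])
    q = np.array([np.cos(0.4), 0, np.sin(0.4), 0])
    pq, qp = quat_multiply(p, q), quat_multiply(q, p)
    assert not np.allclose(pq, qp)
    assert np.linalg.norm(pq) == pytest.approx(1.0)
    np.testing.assert_allclose(quat_multiply(p, quat_conjugate(p)), [1, 0, 0, 0], atol=1e-12)


# ---------------------------------------------------------------------------
# Scalar metrics


def test_horizontal_magnitude_345():
    assert horizontal_magnitude(np.array([3.0, 4.0, 123.0])) == pytest.approx(5.0)
    assert horizontal_magnitude(np.array([0.0, 0.0, 9.8])) == 0.0


@given(seed=st.integers(0, 200))
def test_horizontal_magnitude_matches_loop_oracle(seed):
    A = np.random.default_rng(seed).normal(size=(20, 3))
    got = horizontal_magnitude(A)
    want = [np.sqrt(a[0] ** 2 + a[1] ** 2) for a in A]
    np.testing.assert_allclose(got, want)


def test_rms_examples():
    assert rms(np.full(10, 5.0)) == pytest.approx(5.0)
    assert rms(np.array([0.0, 1.0])) == pytest.approx(np.sqrt(0.5))
    with pytest.raises(ValueError):
        rms(np.array([]))


def test_rms_of_dense_sinusoid_is_amplitude_over_sqrt2():
    t = np.linspace(0, 10, 100000, endpoint=False)  # whole periods at 1 Hz
    A = 3.7
    assert rms(A * np.sin(2 * np.pi * t)) == pytest.approx(A / np.sqrt(2), rel=0.01)


@given(c=st.floats(-10, 10), seed=st.integers(0, 100))
def test_rms_scale_equivariance(c, seed):
    x = np.random.default_rng(seed).normal(size=30)
    assert rms(c * x) == pytest.approx(abs(c) * rms(x), abs=1e-9)


# ---------------------------------------------------------------------------
# Masking and scoring


def make_imu_stream(n=30, fs=10.0, segments=(), accel=None, **kw):
    t = np.arange(n) / fs
    accel = accel if accel is not None else np.tile([0.0, 0.0, 1.0], (n, 1))
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return IMUStream("t0", "M1", "modified", t, accel, quat, list(segments), **kw)


def test_interval_mask_retains_expected_samples():
    stream = make_imu_stream(n=30, fs=10.0, segments=[(1.0, 2.0)])
    mask = mask_active(stream)
    assert mask.sum() == 10
    assert mask[10] and not mask[9] and not mask[20]


def test_empty_segments_produce_no_result(caplog):
    stream = make_imu_stream(segments=[])
    assert stability_score(stream) is None


def test_auto_mask_recovers_block_boundaries():
    fs = 50.0
    n = int(20 * fs)
    t = np.arange(n) / fs
    rng = np.random.default_rng(11)
    moving = (t >= 5.0) & (t < 15.0)
    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    accel[:, 0] += 0.2 * np.sin(2 * np.pi * 1.0 * t) * moving
    accel[:, 2] += 0.2 * np.sin(2 * np.pi * 1.5 * t) * moving  # vertical bounce
    accel += rng.normal(0, 0.002, size=accel.shape)
    stream = make_imu_stream(n=n, fs=fs, accel=accel)
    mask = mask_active(stream, auto=True, window_s=0.5, std_threshold=0.02)
    changes = np.flatnonzero(np.diff(mask.astype(int)))
    boundaries = t[changes]
    assert len(boundaries) >= 2
    assert abs(boundaries[0] - 5.0) < 0.5 and abs(boundaries[-1] - 15.0) < 0.5
    # >=95% of samples classified correctly
    assert (mask == moving).mean() >= 0.95


def test_stability_score_uses_only_active_samples():
    n, fs = 40, 10.0
    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    accel[10:20, 0] = 0.3  # horizontal only inside the active window
    stream = make_imu_stream(n=n, fs=fs, segments=[(1.0, 2.0)], accel=accel)
    res = stability_score(stream)
    assert res.n_samples_used == 10
    assert res.rms_xy == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# Condition comparison


def paired_results(values_mod, values_reg, movement="M1"):
    out = []
    for i, (vm, vr) in enumerate(zip(values_mod, values_reg)):
        out.append(StabilityResult(f"a{i}", movement, "modified", vm, 100, subject=f"S{i}"))
        out.append(StabilityResult(f"b{i}", movement, "regular", vr, 100, subject=f"S{i}"))
    return out

def test_identical_pairs_give_p_one():
    vals = np.linspace(0.1, 0.5, 8)
    out = compare_conditions(paired_results(vals, vals))
    assert out["seated"]["median_diff"] == 0.0
    assert out["seated"]["p_value"] == 1.0
    assert out["seated"]["direction"] == "no difference"


def test_halved_rms_detected_with_exact_signed_rank():
    reg = np.linspace(0.2, 0.4, 10)
    out = compare_conditions(paired_results(reg / 2, reg))
    c = out["seated"]
    assert c["direction"] == "modified < regular"
    assert c["p_value"] < 0.05
    # exact enumeration oracle at n=10: all ranks on one side
    oracle = stats.wilcoxon(reg / 2, reg, alternative="two-sided", mode="exact").pvalue
    assert c["p_value"] == pytest.approx(oracle)


def test_unpaired_results_raise_listing_missing():
    results = paired_results(np.linspace(0.1, 0.2, 6), np.linspace(0.2, 0.3, 6))
    results = results[:-1]  # drop one regular trial
    with pytest.raises(PairingError, match="S5"):
        compare_conditions(results)


def test_too_few_pairs_raise():
    with pytest.raises(PairingError, match="pairs"):
        compare_conditions(paired_results([0.1, 0.2], [0.2, 0.3]))


def test_movement_groups_split_correctly():
    results = []
    for m, val in (("M1", 0.1), ("M5", 0.3), ("M6", 0.2)):
        for i in range(5):
            results.append(StabilityResult(f"m{m}{i}", m, "modified", val + 0.01 * i, 10, subject=f"S{i}"))
            results.append(StabilityResult(f"r{m}{i}", m, "regular", 2 * val + 0.01 * i, 10, subject=f"S{i}"))
    out = compare_conditions(results)
    assert set(out) == {"seated", "stand_up", "standing"}
    assert all(c["direction"] == "modified < regular" for c in out.values())


def test_stability_model_summary_names_test():
    reg = np.linspace(0.2, 0.4, 8)
    model = ChairStabilityModel(paired_results(reg / 2, reg))
    fitted = model.fit()
    text = fitted.summary()
    assert "Wilcoxon signed-rank" in text and "modified < regular" in text
    assert fitted.to_frame().loc["seated", "n_pairs"] == 8


# ---------------------------------------------------------------------------
# I/O


def test_imu_csv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    n = 25
    stream = IMUStream(
        "trial7", "M6", "regular",
        np.arange(n) / 50.0,
        rng.normal(size=(n, 3)),
        np.tile([1.0, 0, 0, 0], (n, 1)),
        subject="S03",
    )
    back = read_imu_csv(write_imu_csv(stream, tmp_path / "imu.csv"))
    assert (back.trial_id, back.movement, back.condition, back.subject) == ("trial7", "M6", "regular", "S03")
    np.testing.assert_allclose(back.accel, stream.accel)
    np.testing.assert_allclose(back.time_s, stream.time_s)


def test_malformed_imu_csv_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("time_s,ax\n0.0,1.0\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_imu_csv(p)


def test_segments_csv_round_trip_and_validation(tmp_path):
    segs = {"t1": [(0.5, 2.0), (3.0, 4.0)], "t2": [(1.0, 1.5)]}
    back = read_segments_csv(write_segments_csv(segs, tmp_path / "seg.csv"))
    assert back == segs
    bad = tmp_path / "bad.csv"
    bad.write_text("trial_id,t_start,t_end\nt1,2.0,1.0\n")
    with pytest.raises(ValueError, match="inverted"):
        read_segments_csv(bad)
    overlap = tmp_path / "overlap.csv"
    overlap.write_text("trial_id,t_start,t_end\nt1,0.0,2.0\nt1,1.0,3.0\n")
    with pytest.raises(ValueError, match="overlap"):
        read_segments_csv(overlap)
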