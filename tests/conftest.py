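import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from exerform.features import FeatureTable, WindowSpec, STAT_NAMES
from exerform.keypoints import KeypointFrame, KeypointStream, Landmark

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


def make_stream(points_per_frame, fps=30.0, trial_id="t0", movement="M1", **kwargs):
    """Build a KeypointStream from {name: [(x, y), ...]} per-frame point lists."""
    n = len(next(iter(points_per_frame.values())))
    frames = []
    for i in range(n):
        lms = {
            name: Landmark(name, float(pts[i][0]), float(pts[i][1]),
                           float(pts[i][2]) if len(pts[i]) > 2 else 1.0)
            for name, pts in points_per_frame.items()
        }
        frames.append(KeypointFrame(frame_index=i, time_s=i / fps, landmarks=lms))
    return KeypointStream(trial_id=trial_id, movement=movement, frames=frames, fps=fps, **kwargs)


def toy_feature_table(X, y, movement="M1", trial_ids=None):
    """FeatureTable over a single channel whose 10 columns hold arbitrary data.

    X may have fewer than 10 columns; remaining columns are filled with a
    deterministic linear combination so every column varies.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    cols = list(STAT_NAMES)
    full = np.zeros((n, 10))
    full[:, :d] = X
    for j in range(d, 10):
        full[:, j] = X[:, j % d] * (0.1 * j + 1.0)
    frame = pd.DataFrame(full, columns=cols)
    frame.insert(0, "trial_id", trial_ids if trial_ids is not None else [f"tr{i}" for i in range(n)])
    frame.insert(1, "movement", movement)
    frame.insert(2, "label", ["correct" if v else "incorrect" for v in y])
    frame.insert(3, "window_index", range(n))
    return FeatureTable(frame=frame, window_spec=WindowSpec(), channel_set=("left_knee_ankle",))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
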