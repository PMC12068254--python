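import numpy as np
import pytest

import wallmotion as wm


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient separable cohort used by several module tests."""
    params = wm.WallMotionParams(separability=2.0)
    manifest, trajs = wm.simulate_cohort(
        2, {"TW": 8, "HR": 8, "unlabeled": 4}, params, seed=7
    )
    return manifest, trajs


@pytest.fixture(scope="session")
def tiny_model():
    cfg = wm.ModelConfig(
        conv_filters=4, lstm_units=5, attention_dim=3, embedding_dim=4, seed=3
    )
    return wm.init_model(cfg)


def helix_trajectory(n=100, rate=100.0, label=0):
    """Unit helix (cos 2πt, sin 2πt, t): analytic speed √(4π²+1), accel 4π²."""
    t = np.arange(n) / rate
    coords = np.c_[np.cos(2 * np.pi * t), np.sin(2 * np.pi * t), t]
    return wm.Trajectory("helix", "p0", label, coords, rate=rate)
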