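import numpy as np
import pytest

import srmdrm as sm


def make_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """Random SPD matrix with eigenvalues spread over ~[1/cond, 1]."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    lam = np.exp(rng.uniform(-np.log(cond), 0.0, size=n))
    return (Q * lam) @ Q.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_session():
    """One easy synthetic session (well-separated classes, low noise)."""
    spec = sm.SimulationSpec(
        n_channels=16,
        sampling_rate=100.0,
        n_trials_per_class=40,
        class_variance_ratio=8.0,
        noise_power=0.05,
        seed=42,
        n_train_trials=40,
        n_test_trials=40,
    )
    train, test, truth = sm.simulate_split(spec)
    cfg = sm.PipelineConfig(seed=42)
    return (
        sm.bandpass_trials(train, cfg),
        sm.bandpass_trials(test, cfg),
        truth,
        cfg,
    )
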