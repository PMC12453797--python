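import numpy as np
import pytest

from learnstate import SynthConfig, synth_dataset


def sine(freq: float, fs: float = 128.0, seconds: float = 4.0, amp: float = 1.0):
    t = np.arange(int(round(seconds * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def small_dataset():
    """Medium-effect synthetic corpus shared across tests (deterministic)."""
    cfg = SynthConfig(n_per_class=12, duration_s=8.0, effect_size=1.5, seed=7)
    _, ds = synth_dataset(cfg)
    return ds


@pytest.fixture(scope="session")
def toy_gaussian():
    """Correlated 2-d Gaussian split into train/held-out halves."""
    rng = np.random.default_rng(42)
    cov = np.array([[1.0, 0.7], [0.7, 1.0]])
    data = rng.multivariate_normal([0.0, 3.0], cov, size=1024)
    return data[:512], data[512:]
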