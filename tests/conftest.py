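import numpy as np
import pytest

from ppgbp import features, synthetic_ppg


@pytest.fixture(scope="session")
def noiseless_config():
    return synthetic_ppg.SynthConfig(
        n_cases=8,
        segments_per_case=4,
        noise_sd=0.0,
        wander_amp=0.0,
        artifact_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return synthetic_ppg.generate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise dataset with a high artifact rate for screening tests."""
    cfg = synthetic_ppg.SynthConfig(
        n_cases=10, segments_per_case=8, artifact_rate=0.3, seed=5
    )
    return synthetic_ppg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_features(noiseless_dataset):
    return features.extract_feature_table([s.segment for s in noiseless_dataset])


def triangle_pulse(n=101):
    """Symmetric triangle 0 → 1 → 0 on n points (n odd keeps the apex exact)."""
    half = n // 2
    up = np.linspace(0.0, 1.0, half + 1)
    return np.concatenate([up, up[-2::-1]])


@pytest.fixture
def triangle():
    return triangle_pulse()
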