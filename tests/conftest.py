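import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prealpha import CANONICAL_CHANNELS, EEGRecord
from prealpha.config import GAConfig, PipelineConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_record(seconds=10.0, fs=200.0, seed=0, scale=20.0):
    """Random 19-channel record (microvolt-scale white noise)."""
    g = np.random.default_rng(seed)
    n = int(seconds * fs)
    return EEGRecord(
        data=scale * g.standard_normal((19, n)),
        sampling_rate=fs,
        channel_labels=CANONICAL_CHANNELS,
        subject_id=f"rec{seed}",
        subject_age=75.0,
        subject_gender="F",
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def tiny_config():
    """Pipeline config with a very small GA, for fast end-to-end tests."""
    return PipelineConfig(ga=GAConfig(population=8, generations=3), seed=7)
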