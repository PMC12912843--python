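import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lakefcc import SceneConfig, datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_config():
    """Small deterministic lake used across unit tests."""
    return SceneConfig(grid_shape=(12, 12), estuary_centres=[(2, 4)], seed=123)


@pytest.fixture
def clean_config():
    """Noise-free, cloud-free variant for exact-recovery tests."""
    return SceneConfig(
        grid_shape=(12, 12),
        estuary_centres=[(2, 4)],
        noise_cv=0.0,
        cloud_fraction=0.0,
        straylight_fraction=0.0,
        sst_noise_sd=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def reference_table():
    """Published 2002-2024 annual FP/FPP/FCCI series."""
    return datasets.load_reference_assessment()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
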