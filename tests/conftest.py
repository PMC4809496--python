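import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import forestchange as fc


@pytest.fixture(scope="session")
def small_scene():
    """A 12x12 scene with all four truth classes (shared across tests)."""
    sampling = fc.SamplingModel(seed=11)
    return fc.generate_scene(12, 12, 40, sampling=sampling)


@pytest.fixture(scope="session")
def clean_sampling():
    """Noise-free, gap-free sampling for exact-recovery tests."""
    return fc.SamplingModel(
        noise_sd=0.0, outlier_prob=0.0, dropout_prob=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noisy_sampling():
    """Default-style noisy sampling with cloud-like outliers."""
    return fc.SamplingModel(
        noise_sd=0.02, outlier_prob=0.05, outlier_shift=-0.1,
        dropout_prob=0.0, mean_revisit=19.5, seed=1,
    )


@pytest.fixture(scope="session")
def training_metrics():
    """Single-band metric vectors for 60/class labelled trajectories."""
    from forestchange.pipeline import simulate_training_metrics

    X, y = simulate_training_metrics(60, bands=("SWIR2",), seed=5)
    return X, y
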