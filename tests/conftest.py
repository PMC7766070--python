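import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20201220)


@pytest.fixture(scope="session")
def single_wave_record():
    """Noise-free record with one southward 10 cm/s planar wave."""
    from ehgprop.synth import WaveSpec, simulate_record

    waves = [WaveSpec(cv_true=10.0, phi_true=0.0, onset_s=30.0)]
    return simulate_record(waves, duration_s=60.0, noise_sd=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def wave_train_record():
    """Three oblique waves with a little noise, annotated."""
    from ehgprop.synth import WaveSpec, simulate_record

    waves = [
        WaveSpec(cv_true=10.0, phi_true=30.0, onset_s=20.0 + 30.0 * i)
        for i in range(3)
    ]
    return simulate_record(waves, duration_s=110.0, noise_sd=0.05, rng_seed=11)
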