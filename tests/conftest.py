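import numpy as np
import pytest
from hypothesis import settings

from boronph.synthetic import ScenarioSpec, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic specimen generated at the default study conditions."""
    return generate(ScenarioSpec(seed=42))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, contamination-free specimen (exact forward model)."""
    spec = ScenarioSpec(
        seed=7,
        measurement_noise=False,
        bca_noise_sd=0.0,
        contam_band_fraction=0.0,
        mgca_amp_noise=0.0,
        growth_jitter=0.0,
    )
    return spec, generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
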