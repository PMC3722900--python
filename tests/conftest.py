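import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ivimtrack as iv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme() -> iv.BValueScheme:
    return iv.BValueScheme.default()


@pytest.fixture(scope="session")
def small_cohort() -> list:
    """Noise-free 4+3 cohort, small enough for per-test reuse."""
    cfg = iv.CohortConfig(seed=11, n_responders=4, n_nonresponders=3,
                          noise_model="none")
    return iv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> list:
    """The default 15+7 cohort at the default Rician SNR."""
    return iv.generate_cohort(iv.CohortConfig(seed=5))


@pytest.fixture()
def image_fixture(scheme):
    tumour = iv.IvimParams(f=0.10, D=1.0e-3, D_star=12e-3, S0=1000.0)
    necrosis = iv.IvimParams(f=0.02, D=2.6e-3, D_star=10e-3, S0=2500.0)
    stack, tmask, nmask = iv.generate_image_fixture(
        (16, 16), tumour, necrosis, scheme, seed=3)
    return stack, tmask, nmask, tumour, necrosis


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
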