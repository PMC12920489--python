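import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrix import simulate

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def training_cohort():
    """Moderate synthetic training cohort with the default effect sizes."""
    cfg = simulate.default_training_config(n_patients=2000, seed=123)
    return simulate.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
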