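import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fdperf.cohort import (CohortConfig, draw_cohort, generating_spec,
                           simulate_paired_dataset)
from fdperf.protocol import CONTROL, CSR

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def control_spec():
    return CONTROL


@pytest.fixture(scope="session")
def csr_spec():
    return CSR


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with zero residual noise and zero random effects."""
    cfg = CohortConfig(n_control=2, n_csr=2, noise_sd=0.0,
                       re_sd_b1=0.0, re_sd_b3=0.0)
    return draw_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def noiseless_paired(noiseless_cohort):
    """Paired design + response generated exactly from the default logistic model."""
    rng = np.random.default_rng(21)
    return simulate_paired_dataset(noiseless_cohort, n_obs=80,
                                   model=generating_spec(), rng=rng,
                                   noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_paired():
    """17-subject cohort with residual noise, no random effects."""
    cfg = CohortConfig(noise_sd=0.2, re_sd_b1=0.0, re_sd_b3=0.0)
    truths = draw_cohort(cfg, seed=3)
    rng = np.random.default_rng(4)
    return simulate_paired_dataset(truths, n_obs=120,
                                   model=generating_spec(), rng=rng,
                                   noise_sd=0.2)
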