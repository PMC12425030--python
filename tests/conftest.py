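import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mwfomics as m
from mwfomics.config import SimConfig

settings.register_profile(
    "fast",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


SMALL = dict(
    n_subjects=50,
    n_proteins=80,
    n_true_pos=6,
    n_true_neg=6,
    frac_specific=0.25,
    samples_per_donor=24,
    n_donors=4,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    """One small synthetic dataset shared (read-only) across tests."""
    return m.simulate_all(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250920)
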