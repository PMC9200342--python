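import numpy as np
import pytest

import homecage as hc


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast tests: 8 animal-weeks of 96 samples."""
    cfg = hc.default_config(seed=11)
    cfg.group_sizes = {"naive": 2, "injured": 3, "sham": 3}
    cfg.weeks = {"naive": (1,), "injured": (1, 2), "sham": (1, 2)}
    cfg.samples_per_week = 96
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return hc.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_observations(small_cohort):
    return hc.bin_observations(small_cohort, n_bins=6)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-conditions cohort: 64 animal-weeks of 290 samples."""
    return hc.generate_cohort(hc.default_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
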