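import numpy as np
import pytest

from stressqtl.simulate import scaled_preset, simulate_cohort


@pytest.fixture(scope="session")
def small_cnur():
    """Scaled-down single-trait cohort shared across module tests."""
    cfg = scaled_preset("cl_cnur", n_individuals=150, n_markers=400)
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_bivar():
    cfg = scaled_preset("cl_bivar", n_individuals=150, n_markers=400)
    return simulate_cohort(cfg, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


def log_trait(cohort, name):
    return np.log(cohort.phenotypes[name].to_numpy(dtype=float))
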