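import numpy as np
import pytest

from riskadapt.synth import CohortConfig, generate_cohort
from riskadapt.fitting import fit_sessions


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced 3-group cohort with all couplings at their defaults."""
    cfg = CohortConfig(
        n_low_mdq=10, n_high_mdq=10, n_bd_lithium=5, n_bd_placebo=5,
        days_volunteer=20, days_bd_baseline=6, days_bd_post=14,
        rng_seed=9,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_fits(small_cohort):
    """MAP session fits for the reduced cohort."""
    _, cohort, _ = small_cohort
    return fit_sessions(cohort.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
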