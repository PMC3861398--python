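import numpy as np
import pytest

from nestmorph import SyntheticCohortSpec, SyntheticImageSpec, generate_cohort, generate_core_image


@pytest.fixture(scope="session")
def clean_core():
    """A noise-free synthetic core with its ground truth (session-cached)."""
    spec = SyntheticImageSpec(n_nests=8, noise_sd=0.0, seed=42)
    return generate_core_image(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose survival is independent of the score (beta = 0)."""
    spec = SyntheticCohortSpec(n_patients=60, log_hr_per_score_unit=0.0,
                               baseline_hazard=0.02, censoring_rate=0.005,
                               seed=7)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
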