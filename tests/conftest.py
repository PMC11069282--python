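import numpy as np
import pytest

from glycostrat import CohortSpec, generate_cohort, simulate_cohort, summarize_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A default-condition cohort (n=120) with its latent covariate frame."""
    return simulate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def cohort_summaries(default_cohort):
    records, _ = default_cohort
    return summarize_cohort(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
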