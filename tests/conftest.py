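import numpy as np
import pytest
from hypothesis import settings

from strkin import normalize_frequencies, simulate_cohort, synth_frequency_table

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table5():
    """Small normalized synthetic table: 5 loci x 6 alleles."""
    return normalize_frequencies(synth_frequency_table(5, 6, 1.0, seed=11))


@pytest.fixture(scope="session")
def cohort_small(table5):
    """40 founders -> 20 families; small enough for exhaustive checks."""
    return simulate_cohort(table5, 40, seed=3)


@pytest.fixture(scope="session")
def cohort_mid(table5):
    """2,000 founders; large enough for 3-SE statistical checks."""
    return simulate_cohort(table5, 2000, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
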