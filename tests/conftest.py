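import numpy as np
import pytest

from hbkg.index import compute_index_table
from hbkg.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 195-patient synthetic cohort, fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_index(default_cohort):
    results, exclusions = compute_index_table(default_cohort.table)
    assert exclusions.empty
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
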