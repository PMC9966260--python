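import numpy as np
import pytest

from qeeg.pipeline import extract_feature_sets
from qeeg.synthetic import SyntheticCohortConfig, generate_cohort

#: One fixed seed for the expensive shared cohort.
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """The default 18/19/13 three-group cohort at 250 Hz, 40 s per subject."""
    return generate_cohort(SyntheticCohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature sets + labels extracted once from the default cohort."""
    return extract_feature_sets(default_cohort.recordings)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
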