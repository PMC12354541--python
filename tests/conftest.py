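import warnings

import numpy as np
import pytest

from lt2lab.simulate import CohortSpec, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_physiology_warnings():
    # age/4-point-fit warnings are informational; keep test output clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """50 noise-free athletes: measured quantities should match ground truth."""
    spec = CohortSpec(n=50, bla_sd=0.0, vo2_cv=0.0, seed=101)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """200 athletes at the default noise level."""
    spec = CohortSpec(n=200, seed=202)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
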