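import logging

import numpy as np
import pytest

from heartprint.synthetic import CohortSpec, generate_cohort

logging.getLogger("heartprint").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects=6, duration_s=45.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def noise_free_spec():
    return CohortSpec(n_subjects=4, duration_s=30.0, seed=11,
                      baseline_wander_amp=0.0, powerline_amp=0.0, broadband_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_spec):
    return generate_cohort(noise_free_spec)
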