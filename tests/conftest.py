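import numpy as np
import pytest

from lesiongraph import build_feature_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20-phantom cohort under the default class presets."""
    return generate_cohort(10, 10, seed=7)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def study_cohort():
    """The default 50+50 study cohort used for end-to-end checks."""
    return generate_cohort(50, 50, seed=0)


@pytest.fixture(scope="session")
def study_table(study_cohort):
    return build_feature_table(study_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
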