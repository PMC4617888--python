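import pytest

from mortbayes import default_baselines
from mortbayes.synthetic_examples import (duhok_cdr_survey, duhok_u5_survey,
                                          high_mortality_prior, skeptical_prior,
                                          yida_survey)


@pytest.fixture(scope="session")
def skeptical():
    return skeptical_prior()


@pytest.fixture(scope="session")
def high_mortality():
    return high_mortality_prior()


@pytest.fixture(scope="session")
def yida():
    return yida_survey()


@pytest.fixture(scope="session")
def duhok_u5():
    return duhok_u5_survey()


@pytest.fixture(scope="session")
def duhok_cdr():
    return duhok_cdr_survey()


@pytest.fixture(scope="session")
def baselines():
    return default_baselines()
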