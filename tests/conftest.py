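import numpy as np
import pytest

from gcci import (
    SyntheticConfig,
    generate_survey,
    community_prevalence,
    fit_one_factor,
    score_communities,
    select_k,
)


@pytest.fixture(scope="session")
def default_survey():
    """The default synthetic fixture: 47 communities, ~20k respondents."""
    return generate_survey(SyntheticConfig())


@pytest.fixture(scope="session")
def small_survey():
    """A cheap survey for unit-level checks."""
    return generate_survey(SyntheticConfig(n_communities=20, n_per_community=120, seed=77))


@pytest.fixture(scope="session")
def default_prevalence(default_survey):
    return community_prevalence(default_survey)


@pytest.fixture(scope="session")
def default_factor(default_prevalence):
    return fit_one_factor(default_prevalence)


@pytest.fixture(scope="session")
def default_scores(default_factor, default_prevalence):
    return score_communities(default_factor, default_prevalence)


@pytest.fixture(scope="session")
def default_gccs(default_scores):
    return select_k(default_scores.score, default_scores.community_id)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
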