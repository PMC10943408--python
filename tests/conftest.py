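import numpy as np
import pytest

from youthpa import (
    CohortSpec,
    MetabolicParams,
    build_cohort,
    load_strata_table,
    synthesize_growth_reference,
    synthesize_markov_params,
)


@pytest.fixture(scope="session")
def table():
    return load_strata_table()


@pytest.fixture(scope="session")
def growth():
    return synthesize_growth_reference(1)


@pytest.fixture(scope="session")
def markov():
    return synthesize_markov_params(1)


@pytest.fixture(scope="session")
def metabolic_params():
    return MetabolicParams()


@pytest.fixture(scope="session")
def small_cohort(table, growth):
    return build_cohort(table, growth, CohortSpec(n_agents=2000, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
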