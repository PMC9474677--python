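import pytest

from ehranon import CohortConfig, MondrianKAnonymizer, generate_cohort, harmonize_cohort
from ehranon.fhir import docs_to_dataset

K_GRID = [5, 10, 15, 20]


@pytest.fixture(scope="session")
def cohort_1k():
    return generate_cohort(CohortConfig(n=1000, seed=1))


@pytest.fixture(scope="session")
def docs_1k(cohort_1k):
    return harmonize_cohort(cohort_1k)


@pytest.fixture(scope="session")
def store_1k(docs_1k):
    return docs_to_dataset(docs_1k, label="S1k")


@pytest.fixture(scope="session")
def model_1k(store_1k):
    return MondrianKAnonymizer(store_1k)


@pytest.fixture(scope="session")
def result_1k_k5(model_1k):
    return model_1k.fit(5)


@pytest.fixture(scope="session")
def store_10k():
    cohort = generate_cohort(CohortConfig(n=10_000, seed=1))
    return docs_to_dataset(harmonize_cohort(cohort), label="S10k")


@pytest.fixture(scope="session")
def sweep_10k(store_10k):
    return MondrianKAnonymizer(store_10k).fit_sweep(K_GRID)
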