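import pytest

from opat_costsim import default_cohort, default_tariffs, DEFAULT_BASE_RATE


@pytest.fixture(scope="session")
def tariffs():
    return default_tariffs()


@pytest.fixture(scope="session")
def cohort(tariffs):
    cases = default_cohort()
    for case in cases:
        case.validate(tariffs)
    return cases


@pytest.fixture(scope="session")
def by_id(cohort):
    return {c.case_id: c for c in cohort}


@pytest.fixture(scope="session")
def base_rate():
    return DEFAULT_BASE_RATE
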