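import warnings

import pytest

from ttvmonitor.synthetic import GeneratorConfig, generate_cohort, make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort, truth = make_fixture("tiny")
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def null_cohort():
    cohort, truth = make_fixture("null")
    return cohort, truth


@pytest.fixture(scope="session")
def dose_cohort():
    cohort, truth = make_fixture("dose_effect")
    return cohort, truth


@pytest.fixture(autouse=True)
def _quiet_skip_warnings():
    # Degenerate-cohort stages emit skip warnings by design; keep test
    # output readable without altering behaviour.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
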