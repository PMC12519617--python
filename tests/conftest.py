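import logging

import pytest

from quadstrat import synthetic


@pytest.fixture(autouse=True)
def _quiet_expected_count_warnings(caplog):
    # sparse fixture tables trip the expected-count<5 warning by design
    logging.getLogger("quadstrat.assoc_stats").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def table3():
    return synthetic.fixture_tables()


@pytest.fixture(scope="session")
def study_params():
    """Study-sized synthetic cohort parameters (small proteome for speed)."""
    return synthetic.SyntheticParams(n_patients=176, n_proteins=40, seed=1)


@pytest.fixture(scope="session")
def study_cohort(study_params):
    clinical = synthetic.generate_clinical(study_params)
    matrix = synthetic.generate_npx(clinical, study_params)
    return clinical, matrix


@pytest.fixture(scope="session")
def big_params():
    """Large-n parameters for law-of-large-numbers calibration checks."""
    return synthetic.SyntheticParams(n_patients=5000, n_proteins=20, seed=11)


@pytest.fixture(scope="session")
def big_cohort(big_params):
    clinical = synthetic.generate_clinical(big_params)
    matrix = synthetic.generate_npx(clinical, big_params)
    return clinical, matrix
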