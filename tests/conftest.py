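import numpy as np
import pytest

from fermopt import datasets, fit_least_squares


@pytest.fixture(scope="session")
def rsm_data():
    """30-run central composite experiment + published predicted column."""
    return datasets.load_rsm_experiment()


@pytest.fixture(scope="session")
def rsm_fit(rsm_data):
    table, _ = rsm_data
    return fit_least_squares(table, "quadratic")


@pytest.fixture(scope="session")
def pbd_reconciled():
    return datasets.load_pbd_screen(reconciled=True)


@pytest.fixture(scope="session")
def pbd_printed():
    return datasets.load_pbd_screen(reconciled=False)


@pytest.fixture(scope="session")
def published_quadratic():
    return datasets.published_quadratic_coefficients()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
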