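import numpy as np
import pytest
from hypothesis import settings

import sizesel as ss

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def perch() -> ss.CatchTable:
    """The bundled Curonian Lagoon perch catch table (raw counts)."""
    return ss.load_perch_catches()


@pytest.fixture(scope="session")
def perch_fit(perch) -> ss.SelectivityResults:
    """Full-pipeline fit of the bundled dataset (normalized per gear)."""
    return ss.SelectivityModel(perch).fit()


@pytest.fixture(scope="session")
def table2_params() -> ss.SelectivityParams:
    """Published point estimates, used where a fit is not under test."""
    return ss.SelectivityParams(0.71, 12.94, 2.13, 0.41)


@pytest.fixture(scope="session")
def perch_population(perch, perch_fit) -> np.ndarray:
    """Data-grounded population composition for simulation designs."""
    return ss.population_from_table(perch, perch_fit.params)
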