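import numpy as np
import pytest

from nitroprof import (
    IsotopeAbundanceTable,
    correction_matrix,
    default_catalog,
    default_tracer_registry,
    parse_formula,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def registry():
    return default_tracer_registry()


@pytest.fixture(scope="session")
def abundances():
    return IsotopeAbundanceTable.default()


@pytest.fixture(scope="session")
def gln_matrix(abundances):
    """Resolved correction matrix for glutamine (2 tracer atoms)."""
    return correction_matrix(parse_formula("C5H10N2O3"), abundances)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
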