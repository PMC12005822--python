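import pytest

from scrca.construct_design import DesignConfig, design_ring
from scrca.fixtures import (
    elp_3ndt_unit,
    elp_unit,
    m10_3ywy_unit,
    make_toy_vector,
    rlp_unit,
)


@pytest.fixture(scope="session")
def elp():
    return elp_unit()


@pytest.fixture(scope="session")
def rlp():
    return rlp_unit()


@pytest.fixture(scope="session")
def e3ndt():
    return elp_3ndt_unit()


@pytest.fixture(scope="session")
def m10ywy():
    return m10_3ywy_unit()


@pytest.fixture(scope="session")
def vector():
    return make_toy_vector()


@pytest.fixture(scope="session")
def e_design(elp, vector):
    return design_ring(elp, DesignConfig(), vector)


@pytest.fixture(scope="session")
def ndt_design(e3ndt, vector):
    return design_ring(e3ndt, DesignConfig(), vector)
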