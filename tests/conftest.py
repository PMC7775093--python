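import pytest
from hypothesis import settings

from humol import fixtures

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def kv_params():
    """Published phantom-calibrated coefficients for the kV beam."""
    return fixtures.published_params("kv")


@pytest.fixture(scope="session")
def mv_params():
    return fixtures.published_params("mv")


@pytest.fixture(scope="session")
def table1():
    return fixtures.table1_materials()


@pytest.fixture(scope="session")
def table2_frame():
    return fixtures.load_fixture("table2")


@pytest.fixture(scope="session")
def attenuation():
    return fixtures.attenuation_table()


@pytest.fixture(scope="session")
def molecules():
    return fixtures.model_molecules()
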