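import pytest

from organopept import (
    SimConfig,
    build_binding_model,
    build_reference_fixture,
    generate_expression,
    generate_proteome,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_proteins=60,
        n_mutations=50,
        peptide_pool_size=2000,
        background_size=1000,
        allotypes=("HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01"),
        seed=11,
    )


@pytest.fixture(scope="session")
def proteome(small_config):
    return generate_proteome(small_config)


@pytest.fixture(scope="session")
def expression(proteome, small_config):
    return generate_expression(proteome, small_config)


@pytest.fixture(scope="session")
def model(small_config):
    return build_binding_model(small_config.allotypes, small_config)


@pytest.fixture(scope="session")
def fixture_data():
    return build_reference_fixture()
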