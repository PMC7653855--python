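import pytest

from alecontam import fixture


@pytest.fixture(scope="session")
def catalog_records():
    return fixture.load_mutation_catalog()


@pytest.fixture(scope="session")
def genotype_matrix():
    return fixture.load_genotype_matrix()


@pytest.fixture(scope="session")
def observations():
    return fixture.load_observations()


@pytest.fixture(scope="session")
def reference_config():
    return fixture.study_reference_config()


@pytest.fixture(scope="session")
def contamination_config():
    return fixture.study_contamination_config()
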