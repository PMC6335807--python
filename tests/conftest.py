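import pytest

from rbchain.races import ANCESTRAL, CHBU, CHHN
from rbchain.synthetic import GeneratorConfig, gen_female_fertility, gen_male_fertility


@pytest.fixture(scope="session")
def chbu():
    return CHBU


@pytest.fixture(scope="session")
def chhn():
    return CHHN


@pytest.fixture(scope="session")
def ancestral():
    return ANCESTRAL


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def male_records(default_config):
    return gen_male_fertility(default_config, seed=11)


@pytest.fixture(scope="session")
def female_records(default_config):
    return gen_female_fertility(default_config, seed=12)
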