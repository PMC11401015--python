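import pytest
from hypothesis import settings

from lidataper import default_drug_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def flupentixol():
    return default_drug_params("flupentixol")


@pytest.fixture(scope="session")
def haloperidol():
    return default_drug_params("haloperidol")


@pytest.fixture(scope="session")
def zuclopenthixol():
    return default_drug_params("zuclopenthixol")


@pytest.fixture(scope="session")
def all_drugs(flupentixol, haloperidol, zuclopenthixol):
    return {
        "flupentixol": flupentixol,
        "haloperidol": haloperidol,
        "zuclopenthixol": zuclopenthixol,
    }
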