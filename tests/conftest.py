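import pytest
from hypothesis import settings

from phytoms import annotator, fragment_rules

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def library():
    return annotator.load_library()


@pytest.fixture(scope="session")
def features():
    return annotator.load_reference_features()


@pytest.fixture(scope="session")
def aglycones():
    return {a.name: a for a in fragment_rules.default_aglycones()}


@pytest.fixture(scope="session")
def rules():
    return fragment_rules.default_rules()
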