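import pytest
from hypothesis import settings

from nanoprecip import datasets

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compounds():
    return datasets.load_compounds()


@pytest.fixture(scope="session")
def design():
    return datasets.load_study_design()


@pytest.fixture(scope="session")
def variant_map():
    return datasets.variant_compound_map()


@pytest.fixture(scope="session")
def protocols_by_variant(design):
    return {v: datasets.build_protocols(v, design=design) for v in design}
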