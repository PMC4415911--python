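import pytest

from hcpanel import fixtures
from hcpanel.simulate import distractor_panel, make_distractors


@pytest.fixture(scope="session")
def study_variants():
    return fixtures.load_variants()


@pytest.fixture(scope="session")
def study_panel():
    return fixtures.load_panel()


@pytest.fixture(scope="session")
def study_curation():
    return fixtures.load_curation()


@pytest.fixture(scope="session")
def study_flags():
    return fixtures.load_flags()


@pytest.fixture(scope="session")
def merged_panel(study_panel):
    # distractor genes first so study entries win on overlap
    return {**distractor_panel(), **study_panel}


@pytest.fixture(scope="session")
def distractors():
    return make_distractors(60, seed=11)


@pytest.fixture(scope="session")
def marker_records():
    return fixtures.load_marker_records()


@pytest.fixture(scope="session")
def family22():
    return fixtures.load_family("22")


@pytest.fixture(scope="session")
def family49():
    return fixtures.load_family("49")
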