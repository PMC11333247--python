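import pytest

from epirisk import fixtures
from epirisk.riskmatrix import default_risk_matrix


@pytest.fixture(scope="session")
def matrix():
    return default_risk_matrix()


@pytest.fixture(scope="session")
def stages():
    return {sid: fixtures.paper_stage(sid) for sid in fixtures.STAGE_IDS}


@pytest.fixture(scope="session")
def goldens():
    return fixtures.printed_goldens()
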