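import pytest

from cnrescan.motif import cnre_reference
from cnrescan.seqcore import ScoringScheme


@pytest.fixture(scope="session")
def motif():
    return cnre_reference()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()
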