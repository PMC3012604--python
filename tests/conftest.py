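import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from immclass.align import DEFAULT_SCHEME
from immclass.seqio import load_references


@pytest.fixture(scope="session")
def refs():
    return load_references()


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME
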