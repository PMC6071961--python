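import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tablesig.tables import HypothesisSpec


@pytest.fixture(scope="session")
def hom22():
    return HypothesisSpec.homogeneity(2, 2)


@pytest.fixture(scope="session")
def ind22():
    return HypothesisSpec.independence(2, 2)


@pytest.fixture(scope="session")
def hwe():
    return HypothesisSpec.hwe()
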