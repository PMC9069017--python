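import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from polascreen.signature import load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()
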