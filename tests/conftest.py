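import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracle helper

from becorrect import builtin_registry

BE3_NAME = "BE1/BE2/BE3/HF-BE3/BE4(max)/BE4-Gam"


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def be3_only(registry):
    return registry.subset([BE3_NAME])


@pytest.fixture(scope="session")
def abe710_only(registry):
    return registry.subset(["ABE 7.10"])
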