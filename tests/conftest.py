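import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hiffl.dynamics import CircuitSpec, IFFLParams


@pytest.fixture(params=[1, 2, 3, 4], ids=lambda t: f"type{t}")
def iffl_type(request):
    return request.param


@pytest.fixture(params=["multiplicative", "additive"])
def mode(request):
    return request.param


@pytest.fixture
def circuit(iffl_type, mode):
    """One of the 8 (type, mode) circuits at baseline parameters."""
    return CircuitSpec(iffl_type, mode, IFFLParams())
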