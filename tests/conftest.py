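import numpy as np
import pytest

from clamploop.preparations import ElectrodeParams
from clamploop.protocols import ProtocolConfig


@pytest.fixture
def passive_cfg():
    """Passive-membrane preparation config at the default engine step."""
    return ProtocolConfig(
        protocol="arbitrary_stream_and_record", preparation="passive", dt=5e-5, seed=3
    )


@pytest.fixture
def electrode_10M():
    return ElectrodeParams(R_s=10e6, C_e=1e-12)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
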