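import numpy as np
import pytest

from dyadpredict.cardiac import IBISeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ibi(ibi_ms, t0_s: float = 0.0) -> IBISeries:
    return IBISeries.from_ibi_ms(np.asarray(ibi_ms, dtype=float), t0_s=t0_s)


@pytest.fixture
def ibi_factory():
    return make_ibi
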