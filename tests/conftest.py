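import numpy as np
import pytest

from breathlock import gen_cardiac_rr, gen_coupled_bold, gen_respiration


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def resp_trace():
    """One deterministic 10-min respiration trace at study conditions."""
    return gen_respiration(0.31, 0.04, 600, 50, seed=7)


@pytest.fixture(scope="session")
def coupled_pair(resp_trace):
    """Respiration plus a BOLD series whose ROI 0 is entrained to it."""
    bold = gen_coupled_bold(resp_trace, 3, 2.0, 20.0, [0], 0.65, seed=8)
    return resp_trace, bold


@pytest.fixture(scope="session")
def cardiac():
    return gen_cardiac_rr(69.0, 17.0, 600, seed=9)
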