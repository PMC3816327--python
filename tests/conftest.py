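import numpy as np
import pytest

from v1facedecode.glm import HrfParams, double_gamma_hrf


@pytest.fixture(scope="session")
def hrf():
    """Canonical double-gamma kernel at TR = 1 s (32 s support)."""
    return double_gamma_hrf(tr=1.0)


@pytest.fixture(scope="session")
def hrf20():
    """Kernel truncated to 20 taps so a 20-bin FIR window covers it exactly."""
    return double_gamma_hrf(tr=1.0, params=HrfParams(length=19.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
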