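import numpy as np
import pytest

from odorgaze.calcium import EpochDesign
from odorgaze.sysid import ImpulseKernel, double_exp_kernel


@pytest.fixture
def default_design():
    return EpochDesign()


@pytest.fixture
def exact_kernel():
    """Noise-free difference-of-exponentials kernel on the default lag grid."""
    lag = np.arange(0, 1.0 + 1e-9, 0.01)
    g = double_exp_kernel(lag, 1.0, 0.02, 0.15)
    return ImpulseKernel(lag=lag, g=g)


def brute_force_convolution(x, g):
    """Independent O(N*K) causal convolution oracle."""
    n, k = len(x), len(g)
    y = np.zeros(n)
    for t in range(n):
        for j in range(min(k, t + 1)):
            y[t] += g[j] * x[t - j]
    return y
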