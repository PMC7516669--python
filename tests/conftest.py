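import numpy as np
import pytest


@pytest.fixture(scope="session")
def pair_truncation():
    """Analytic truncated-recursion sequence for the dependent pair.

    Computed once per session by deterministic quadrature; element q-1
    is the estimate keeping q recursion levels of marginal entropies.
    """
    from cadee.analytic import pair_truncation_sequence

    return pair_truncation_sequence(levels=3, grid=1025)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
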