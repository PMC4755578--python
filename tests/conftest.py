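import numpy as np
import pytest

from infomaxnet import NetworkParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_subcritical_network(rng, M=5, N=2, coupling=0.3):
    """A random network safely inside the subcritical regime.

    Recurrent entries of scale ``coupling / sqrt(M)`` keep the spectral
    radius of GK well below 1 for the logistic (gains <= 1/4).
    """
    W = rng.standard_normal((M, N))
    K = coupling / np.sqrt(M) * rng.standard_normal((M, M))
    return NetworkParams(W=W, K=K)
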