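import numpy as np
import pytest
from scipy import sparse

from modular_esn import ActivationParams, GraphSpec, Reservoir, generate_graph


@pytest.fixture
def small_spec():
    """A 60-node graph with 6 communities of 10, in-degree 4."""
    return GraphSpec(n_nodes=60, n_communities=6, community_size=10, degree=4, mu=0.2, seed=7)


@pytest.fixture
def small_graph(small_spec):
    return generate_graph(small_spec)


@pytest.fixture
def tiny_reservoir():
    """A fixed 5-node reservoir with known weights for oracle checks."""
    rng = np.random.default_rng(11)
    W = sparse.csr_array(rng.normal(scale=0.3, size=(5, 5)))
    W_in = rng.normal(size=(5, 2))
    return Reservoir(W=W, W_in=W_in, activation=ActivationParams.threshold())
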