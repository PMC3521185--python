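import numpy as np
import pytest

from swcnet.types import CompositeNetwork


def make_weighted_network(weights):
    """Build a single-feature network with explicit edge weights.

    ``weights`` maps (u, v) tuples to the posterior weight to assign.
    """
    net = CompositeNetwork(["w"])
    for (u, v), w in weights.items():
        net.add_edge(u, v, {"w": w if w > 0 else 1.0})
        net.edge_data(u, v)["weight"] = float(w)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
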