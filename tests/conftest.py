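import numpy as np
import pytest

from thermoflux import DirectionAssignment, PotentialVector, ReactionNetwork


@pytest.fixture
def ab_network():
    """Single reaction A -> B."""
    return ReactionNetwork(["A", "B"], ["r1"], [[-1.0], [1.0]], [False])


@pytest.fixture
def chain_network():
    """Chain A -> B -> C, both irreversible forward."""
    S = [[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]]
    return ReactionNetwork(["A", "B", "C"], ["r1", "r2"], S, [False, False])


@pytest.fixture
def cycle_network():
    """Directed 3-cycle A -> B -> C -> A; infeasible when all run forward."""
    S = [[-1.0, 0.0, 1.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
    return ReactionNetwork(["A", "B", "C"], ["r1", "r2", "r3"], S, [True, True, True])


@pytest.fixture
def forward(request):
    def _forward(network):
        return DirectionAssignment(np.ones(network.N, dtype=int))
    return _forward


def zeros_mu(m):
    return PotentialVector.zeros(m)
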