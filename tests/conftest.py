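import numpy as np
import pytest

from drivenrnn import NetworkSpec, Reservoir, build_reservoir


def reservoir_from_arrays(weights, input_weights, gain=1.0, seed=0) -> Reservoir:
    """Wrap explicit weight arrays in a Reservoir for closed-form tests."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    n = weights.shape[0]
    spec = NetworkSpec(n_neurons=n, connection_prob=1.0, gain=gain, seed=seed)
    return Reservoir(
        weights=weights,
        input_weights=np.asarray(input_weights, dtype=float).ravel(),
        spec=spec,
    )


@pytest.fixture
def single_neuron():
    """One neuron, no recurrence, unit input weight: phi(s) = s."""
    return reservoir_from_arrays([[0.0]], [1.0])


@pytest.fixture(scope="session")
def stable_small():
    """Small stable network reused across tests (N=60, g=0.9)."""
    return build_reservoir(NetworkSpec(60, 0.2, 0.9, 1234))


@pytest.fixture(scope="session")
def stable_n200():
    """The protocol-sized stable network (N=200, p=0.1, g=0.9)."""
    return build_reservoir(NetworkSpec(200, 0.1, 0.9, 99))
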