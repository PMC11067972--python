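import numpy as np
import pytest

from csbp.lif import LIFParams, NetworkWeights


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return LIFParams(k_tau=0.25, v_th=0.5, T=8)


@pytest.fixture
def small_net(rng):
    return NetworkWeights.init_uniform([2, 3, 2], rng=rng)


@pytest.fixture
def xor_targets():
    return np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0]])


def scalar_forward_oracle(weight_mats, input_spikes, k_tau, v_th, T):
    """Plain-Python scalar-loop re-implementation of the LIF forward pass."""
    layers_O = [input_spikes.tolist()]
    layers_V = [[[0.0] * T for _ in input_spikes]]
    prev = input_spikes.tolist()
    for W in weight_mats:
        n = len(W)
        V = [[0.0] * T for _ in range(n)]
        O = [[0.0] * T for _ in range(n)]
        for t in range(T):
            for j in range(n):
                drive = W[j][0]  # bias channel
                for k in range(len(prev)):
                    drive += W[j][k + 1] * prev[k][t]
                v_prev = V[j][t - 1] if t > 0 else 0.0
                o_prev = O[j][t - 1] if t > 0 else 0.0
                v = k_tau * v_prev * (1.0 - o_prev) + drive
                V[j][t] = v
                O[j][t] = 1.0 if v >= v_th else 0.0
        layers_O.append(O)
        layers_V.append(V)
        prev = O
    return layers_O, layers_V
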