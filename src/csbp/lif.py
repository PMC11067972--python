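"""Discrete-time leaky integrate-and-fire network simulation.

The forward model, per computing layer ``i`` and step ``t``, is

    V[t+1] = k_tau * V[t] * (1 - O[t]) + sum_k w[j, k] * O_prev[k, t+1]
    O[t+1] = step(V[t+1] - v_th)

with hard reset through the ``(1 - O[t])`` carry factor, a constant-1
bias channel at presynaptic index ``k = 0``, zero initial potentials,
and the step function spiking at threshold equality.  ``smooth=True``
replaces the step with a sigmoid relaxation; gradient-checking oracles
rely on that mode.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

__all__ = [
    "LIFParams",
    "NetworkWeights",
    "SpikeRecord",
    "lif_step",
    "simulate_forward",
    "forward_arrays",
    "encode_constant",
    "encode_poisson",
    "rate_decode",
]


@dataclasses.dataclass(frozen=True)
class LIFParams:
    """Neuron constants: decay factor, firing threshold, horizon."""

    k_tau: float = 0.25
    v_th: float = 0.5
    T: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.k_tau < 1.0):
            raise ValueError(f"k_tau must lie in (0, 1), got {self.k_tau}")
        if not self.v_th > 0.0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 1):
            raise ValueError(f"T must be a positive integer, got {self.T}")


@dataclasses.dataclass
class NetworkWeights:
    """Layered weight matrices; column 0 of each matrix is the bias.

    ``weights[i]`` has shape ``(layer_sizes[i + 1], layer_sizes[i] + 1)``.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(m) for m in self.layer_sizes)
        if any(m < 1 for m in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError(
                f"expected {len(self.layer_sizes) - 1} weight matrices, "
                f"got {len(self.weights)}"
            )
        mats = []
        for i, w in enumerate(self.weights):
            w = np.asarray(w, dtype=float)
            want = (self.layer_sizes[i + 1], self.layer_sizes[i] + 1)
            if w.shape != want:
                raise ValueError(
                    f"weight matrix {i} has shape {w.shape}, expected {want}"
                )
            if not np.all(np.isfinite(w)):
                raise ValueError(f"weight matrix {i} contains non-finite entries")
            mats.append(w)
        self.weights = mats

    @classmethod
    def init_uniform(
        cls,
        layer_sizes: Sequence[int],
        low: float = -1.0,
        high: float = 1.0,
        rng: np.random.Generator | int | None = None,
    ) -> "NetworkWeights":
        """Uniform init on ``[low, high]`` for every weight and bias."""
        rng = np.random.default_rng(rng)
        sizes = tuple(int(m) for m in layer_sizes)
        mats = [
            rng.uniform(low, high, size=(sizes[i + 1], sizes[i] + 1))
            for i in range(len(sizes) - 1)
        ]
        return cls(sizes, mats)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.layer_sizes, [w.copy() for w in self.weights])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights])

    def with_vector(self, vec: np.ndarray) -> "NetworkWeights":
        """New instance with the same shapes, entries taken from ``vec``."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_params:
            raise ValueError(f"vector has {vec.size} entries, need {self.n_params}")
        mats, k = [], 0
        for w in self.weights:
            mats.append(vec[k : k + w.size].reshape(w.shape).copy())
            k += w.size
        return NetworkWeights(self.layer_sizes, mats)

    def to_json(self, path: str) -> None:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "NetworkWeights":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["layer_sizes"]),
            [np.asarray(w, dtype=float) for w in payload["weights"]],
        )


@dataclasses.dataclass
class SpikeRecord:
    """One forward simulation: spikes ``O`` and potentials ``V`` per layer.

    ``O[i]`` has shape ``(M_i + 1, T)`` with the constant-1 bias channel
    at row 0 (layer 0 is the input).  ``V[i]`` has shape ``(M_i, T)``;
    ``V[0]`` is identically zero (inputs carry no potential).
    """

    O: list[np.ndarray]
    V: list[np.ndarray]
    params: LIFParams

    @property
    def n_layers(self) -> int:
        return len(self.O) - 1

    def spikes(self, layer: int) -> np.ndarray:
        """Spike matrix of a layer without the bias row, shape (M, T)."""
        return self.O[layer][1:, :]

    def to_csv(self, path: str) -> None:
        import pandas as pd

        rows = []
        for i in range(len(self.O)):
            spikes = self.spikes(i)
            volts = self.V[i]
            for j in range(spikes.shape[0]):
                for t in range(spikes.shape[1]):
                    rows.append((i, j + 1, t + 1, volts[j, t], spikes[j, t]))
        pd.DataFrame(rows, columns=["layer", "neuron", "t", "V", "O"]).to_csv(
            path, index=False
        )


def lif_step(
    V: float, spiked_prev: float, drive: float, params: LIFParams
) -> tuple[float, int]:
    """Single-neuron update: decayed, reset-gated carry plus drive."""
    V = float(V)
    spiked_prev = float(spiked_prev)
    drive = float(drive)
    if not (np.isfinite(V) and np.isfinite(spiked_prev) and np.isfinite(drive)):
        raise ValueError("lif_step inputs must be finite")
    v_next = params.k_tau * V * (1.0 - spiked_prev) + drive
    o_next = 1 if v_next >= params.v_th else 0
    return v_next, o_next


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward_arrays(
    weight_mats: Sequence[np.ndarray],
    inputs: np.ndarray,
    params: LIFParams,
    smooth: bool = False,
    width: float = 1.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Batched forward pass on raw arrays.

    Parameters
    ----------
    weight_mats : per-layer matrices ``(M_i, M_{i-1} + 1)``, bias column 0.
    inputs : spike tensor ``(B, M_0, T)``.
    smooth : replace the step function with ``sigmoid((V - v_th)/width)``.

    Returns ``(O_layers, V_layers)``, each a list over layers 0..l of
    ``(B, M_i, T)`` arrays (no bias rows; ``V_layers[0]`` is zero).
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3:
        raise ValueError("inputs must have shape (batch, M_0, T)")
    B, m0, T = inputs.shape
    if m0 != weight_mats[0].shape[1] - 1:
        raise ValueError(
            f"input has {m0} channels, first layer expects "
            f"{weight_mats[0].shape[1] - 1}"
        )
    if T != params.T:
        raise ValueError(f"input horizon {T} != params.T {params.T}")

    O_layers = [inputs]
    V_layers = [np.zeros_like(inputs)]
    o_prev = inputs
    for W in weight_mats:
        mi = W.shape[0]
        V = np.empty((B, mi, T))
        O = np.empty((B, mi, T))
        v = np.zeros((B, mi))
        o = np.zeros((B, mi))
        wt = W[:, 1:].T
        bias = W[:, 0]
        for t in range(T):
            v = params.k_tau * v * (1.0 - o) + o_prev[:, :, t] @ wt + bias
            if smooth:
                o = _sigmoid((v - params.v_th) / width)
            else:
                o = (v >= params.v_th).astype(float)
            V[:, :, t] = v
            O[:, :, t] = o
        O_layers.append(O)
        V_layers.append(V)
        o_prev = O
    return O_layers, V_layers


def simulate_forward(
    weights: NetworkWeights, input_spikes: np.ndarray, params: LIFParams
) -> SpikeRecord:
    """Simulate the full network for one sample; see module docstring.

    ``input_spikes`` is binary with shape ``(M_0, T)``.
    """
    input_spikes = np.asarray(input_spikes, dtype=float)
    if input_spikes.shape != (weights.layer_sizes[0], params.T):
        raise ValueError(
            f"input spikes have shape {input_spikes.shape}, expected "
            f"{(weights.layer_sizes[0], params.T)}"
        )
    if not np.all(np.isin(input_spikes, (0.0, 1.0))):
        raise ValueError("input spikes must be binary")
    O_layers, V_layers = forward_arrays(
        weights.weights, input_spikes[None, :, :], params
    )
    ones = np.ones((1, params.T))
    O = [np.vstack([ones, o[0]]) for o in O_layers]
    V = [v[0] for v in V_layers]
    return SpikeRecord(O=O, V=V, params=params)


def encode_constant(x: np.ndarray, T: int) -> np.ndarray:
    """Bit 1 -> spike at every step; bit 0 -> silent.  Shape ``(M, T)``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D bit vector")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("x entries must be 0 or 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    return np.repeat(x[:, None], T, axis=1)


def encode_poisson(
    x: np.ndarray, T: int, rng: np.random.Generator | int | None
) -> np.ndarray:
    """Bernoulli spikes with per-step probability ``x_m`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    return (rng.random((x.size, T)) < x[:, None]).astype(float)


def rate_decode(record: SpikeRecord, layer: int) -> np.ndarray:
    """Per-neuron mean firing rate of a layer (bias row excluded)."""
    if not 0 <= layer < len(record.O):
        raise IndexError(f"layer {layer} out of range")
    return record.spikes(layer).mean(axis=1)
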