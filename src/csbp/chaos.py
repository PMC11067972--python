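"""Neuron-intrinsic chaotic loss, its analytic gradient, and annealing.

Each masked neuron contributes ``-z * (I0*ln(h) + (1 - I0)*ln(1 - h))``
where ``h = sigmoid`` of the neuron's time-averaged weighted drive
(including the constant-1 bias channel).  The weight gradient of this
term factorizes to ``-z * (I0 - h) * s_k`` with ``s_k`` the mean
presynaptic activity; the ``h (1 - h)`` cancellation is implemented
analytically, never through the quotient.  Annealing is the geometric
decay ``z <- beta * z``.  A logistic-map source is provided as an
external-chaos ablation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .lif import SpikeRecord, _sigmoid

__all__ = [
    "ChaosConfig",
    "HiddenActivity",
    "mean_presyn_activity",
    "hidden_activity",
    "chaotic_loss_value",
    "chaotic_gradient",
    "anneal",
    "logistic_chaos_term",
    "chaos_terms_arrays",
]

_H_CLIP = 1e-12


@dataclasses.dataclass
class ChaosConfig:
    """Chaos intensity state and schedule.

    ``mask`` is either ``None`` (every neuron in every computing layer)
    or an iterable of 1-based ``(layer, neuron)`` pairs.  ``include_bias``
    controls whether the bias column receives the chaotic gradient (the
    drive inside ``h`` always includes the bias).
    """

    z0: float = 20.0
    beta: float = 0.9995
    I0: float = 0.65
    mask: tuple[tuple[int, int], ...] | None = None
    include_bias: bool = True
    anneal_granularity: str = "per_batch"

    def __post_init__(self) -> None:
        if not self.z0 >= 0:
            raise ValueError("z0 must be nonnegative")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if not (0.0 < self.I0 < 1.0):
            raise ValueError("I0 must lie in (0, 1)")
        if self.anneal_granularity not in ("per_batch", "per_epoch"):
            raise ValueError(
                f"unknown anneal granularity {self.anneal_granularity!r}"
            )
        if self.mask is not None:
            self.mask = tuple((int(i), int(j)) for i, j in self.mask)
            for i, j in self.mask:
                if i < 1 or j < 1:
                    raise ValueError("mask pairs are 1-based (layer, neuron)")

    def mask_arrays(self, layer_sizes: Sequence[int]) -> list[np.ndarray]:
        """Per-computing-layer boolean vectors over neurons."""
        sizes = list(layer_sizes)[1:]
        if self.mask is None:
            return [np.ones(m, dtype=bool) for m in sizes]
        out = [np.zeros(m, dtype=bool) for m in sizes]
        for i, j in self.mask:
            if i > len(sizes) or j > sizes[i - 1]:
                raise ValueError(f"mask entry ({i}, {j}) outside the network")
            out[i - 1][j - 1] = True
        return out


@dataclasses.dataclass
class HiddenActivity:
    """Sigmoid activity ``h`` of one neuron with its presynaptic means."""

    h: float
    s: np.ndarray


def mean_presyn_activity(record: SpikeRecord, layer: int) -> np.ndarray:
    """Mean presynaptic spike activity feeding ``layer``.

    Entry ``k`` is the time average of channel ``k`` of layer
    ``layer - 1``; ``k = 0`` is the bias channel, identically 1.
    """
    if not 1 <= layer <= record.n_layers:
        raise IndexError(f"layer {layer} out of range 1..{record.n_layers}")
    return record.O[layer - 1].mean(axis=1)


def hidden_activity(weights_row: np.ndarray, s: np.ndarray) -> float:
    """``sigmoid`` of the time-averaged drive ``<w, s>``."""
    w = np.asarray(weights_row, dtype=float)
    s = np.asarray(s, dtype=float)
    if w.shape != s.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {s.shape}")
    return float(_sigmoid(np.atleast_1d(w @ s))[0])


def chaotic_loss_value(h: float, z: float, I0: float) -> float:
    """Cross-entropy-form chaotic loss of one neuron; minimum at h = I0."""
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must lie in (0, 1), got {h}")
    if z < 0:
        raise ValueError("z must be nonnegative")
    hc = min(max(h, _H_CLIP), 1.0 - _H_CLIP)
    return float(-z * (I0 * np.log(hc) + (1.0 - I0) * np.log(1.0 - hc)))


def chaotic_gradient(z: float, I0: float, h: float, s_k: float) -> float:
    """Analytic weight gradient ``-z * (I0 - h) * s_k`` of the chaotic loss."""
    if not (np.isfinite(z) and np.isfinite(I0) and np.isfinite(h) and np.isfinite(s_k)):
        raise ValueError("chaotic_gradient inputs must be finite")
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must lie in (0, 1), got {h}")
    return float(-z * (I0 - h) * s_k)


def anneal(z: float, beta: float) -> float:
    """One geometric annealing step ``z <- beta * z``."""
    if z < 0:
        raise ValueError("z must be nonnegative")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    return beta * z


def logistic_chaos_term(state: float, z: float) -> tuple[float, float]:
    """External-chaos ablation step driven by the logistic map at r = 4.

    Returns ``(perturbation, next_state)`` with
    ``next_state = 4 * state * (1 - state)`` and the zero-mean
    perturbation ``z * (next_state - 0.5)`` injected in place of the
    intrinsic chaotic gradient term.
    """
    if not 0.0 < state < 1.0:
        raise ValueError(f"logistic state must lie in (0, 1), got {state}")
    next_state = 4.0 * state * (1.0 - state)
    return z * (next_state - 0.5), next_state


def chaos_terms_arrays(
    weight_mats: Sequence[np.ndarray],
    O_layers: Sequence[np.ndarray],
    z: float,
    I0: float,
    mask_arrays: Sequence[np.ndarray] | None = None,
    include_bias: bool = True,
) -> tuple[float, list[np.ndarray]]:
    """Batched chaotic loss and per-layer weight gradients.

    ``O_layers`` are the raw (bias-free) spike tensors of a batched
    forward pass; the batch mean is taken over both loss and gradient.
    Rows outside the mask contribute zero.
    """
    loss = 0.0
    grads: list[np.ndarray] = []
    for i, W in enumerate(weight_mats):
        B = O_layers[i].shape[0]
        s = np.concatenate(
            [np.ones((B, 1)), O_layers[i].mean(axis=2)], axis=1
        )  # (B, M_prev + 1)
        h = _sigmoid(s @ W.T)  # (B, M_i)
        active = (
            np.ones(W.shape[0], dtype=bool) if mask_arrays is None else mask_arrays[i]
        )
        if z != 0.0 and active.any():
            hc = np.clip(h[:, active], _H_CLIP, 1.0 - _H_CLIP)
            loss += float(
                -z * (I0 * np.log(hc) + (1.0 - I0) * np.log(1.0 - hc)).sum() / B
            )
        g = (-z * (I0 - h))[:, :, None] * s[:, None, :]
        g = g.mean(axis=0)
        g[~active, :] = 0.0
        if not include_bias:
            g[:, 0] = 0.0
        grads.append(g)
    return loss, grads
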