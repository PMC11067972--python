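"""Surrogate-gradient backpropagation through time.

The backward pass unrolls the LIF recursion over ``t = T..1``, replacing
the derivative of the spike step with a surrogate window and, by
default, treating the reset factor ``(1 - O[t])`` as a constant.
``reset_mode="surrogate"`` differentiates the reset path as well, which
together with the smooth forward relaxation makes the pass an exact
gradient of the relaxed network (the finite-difference oracle used in
tests relies on this).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .lif import LIFParams, NetworkWeights, SpikeRecord, forward_arrays, rate_decode

__all__ = [
    "SurrogateSpec",
    "LossSpec",
    "surrogate_derivative",
    "loss_bp_value",
    "backprop_bptt",
    "bp_update",
    "loss_and_grad_arrays",
    "export_gradients_csv",
]

_SURROGATE_KINDS = ("rectangular", "sigmoid_derivative")
_LOSS_KINDS = ("mse_rate", "cross_entropy_rate", "zero")


@dataclasses.dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate derivative for the spike nonlinearity.

    ``rectangular``: ``1/width`` on ``|u| <= width/2``, else 0.
    ``sigmoid_derivative``: ``sigma'(u/width)/width``.
    """

    kind: str = "rectangular"
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _SURROGATE_KINDS:
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if not self.width > 0:
            raise ValueError("surrogate width must be positive")


@dataclasses.dataclass(frozen=True)
class LossSpec:
    """Task loss on decoded output rates.

    ``mse_rate`` is the mean squared error between output firing rates
    and the target vector; ``cross_entropy_rate`` applies softmax to the
    rates first; ``zero`` is the constant-zero loss (chaos-only runs).
    """

    kind: str = "mse_rate"
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in _LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind != "zero" and self.target is None:
            raise ValueError("target required for non-zero losses")
        if self.target is not None:
            object.__setattr__(
                self, "target", np.asarray(self.target, dtype=float)
            )


def surrogate_derivative(u: np.ndarray | float, spec: SurrogateSpec):
    """Surrogate value at membrane offset ``u = V - v_th``."""
    u = np.asarray(u, dtype=float)
    if spec.kind == "rectangular":
        out = np.where(np.abs(u) <= spec.width / 2.0, 1.0 / spec.width, 0.0)
    else:
        x = u / spec.width
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        out = s * (1.0 - s) / spec.width
    return out if out.ndim else float(out)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _loss_and_output_grad(
    O_out: np.ndarray, targets: np.ndarray | None, kind: str
) -> tuple[float, np.ndarray]:
    """Batch-mean loss and d loss / d O for the output spike tensor."""
    B, n_out, T = O_out.shape
    if kind == "zero":
        return 0.0, np.zeros_like(O_out)
    if targets.shape != (B, n_out):
        raise ValueError(
            f"targets have shape {targets.shape}, expected {(B, n_out)}"
        )
    rates = O_out.mean(axis=2)
    if kind == "mse_rate":
        diff = rates - targets
        loss = float((diff**2).sum() / (B * n_out))
        d_rates = 2.0 * diff / (B * n_out)
    elif kind == "cross_entropy_rate":
        p = _softmax(rates)
        loss = float(-(targets * np.log(np.clip(p, 1e-300, None))).sum() / B)
        d_rates = (p - targets) / B
    else:  # pragma: no cover
        raise ValueError(kind)
    return loss, np.repeat(d_rates[:, :, None] / T, T, axis=2)


def backward_arrays(
    weight_mats: Sequence[np.ndarray],
    O_layers: Sequence[np.ndarray],
    V_layers: Sequence[np.ndarray],
    dL_dO_out: np.ndarray,
    params: LIFParams,
    sg: SurrogateSpec,
    reset_mode: str = "constant",
) -> list[np.ndarray]:
    """BPTT on raw batched arrays; returns per-layer gradient matrices.

    ``dL_dO_out`` has shape ``(B, M_l, T)``; gradients are already summed
    over the batch (callers bake the batch mean into ``dL_dO_out``).
    """
    if reset_mode not in ("constant", "surrogate"):
        raise ValueError(f"unknown reset_mode {reset_mode!r}")
    k_tau = params.k_tau
    n_layers = len(weight_mats)
    T = params.T
    grads: list[np.ndarray] = [None] * n_layers
    dLdO = dL_dO_out
    for i in range(n_layers - 1, -1, -1):
        W = weight_mats[i]
        V = V_layers[i + 1]
        O = O_layers[i + 1]
        O_prev = O_layers[i]
        B, mi, _ = V.shape
        dLdV = np.empty((B, mi, T))
        dv_next = np.zeros((B, mi))
        for t in range(T - 1, -1, -1):
            v_t = V[:, :, t]
            sg_t = surrogate_derivative(v_t - params.v_th, sg)
            local = dLdO[:, :, t]
            if reset_mode == "surrogate":
                local = local - dv_next * (k_tau * v_t)
            dv = local * sg_t + dv_next * (k_tau * (1.0 - O[:, :, t]))
            dLdV[:, :, t] = dv
            dv_next = dv
        g = np.empty_like(W)
        g[:, 0] = dLdV.sum(axis=(0, 2))
        g[:, 1:] = np.einsum("bmt,bkt->mk", dLdV, O_prev)
        grads[i] = g
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in layer {i + 1}")
        if i > 0:
            dLdO = np.einsum("bmt,mk->bkt", dLdV, W[:, 1:])
    return grads


def loss_and_grad_arrays(
    weight_mats: Sequence[np.ndarray],
    inputs: np.ndarray,
    targets: np.ndarray | None,
    params: LIFParams,
    sg: SurrogateSpec,
    loss_kind: str = "mse_rate",
    reset_mode: str = "constant",
    smooth: bool = False,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Forward + backward on raw arrays.

    Returns ``(loss, grads, O_layers)``; ``O_layers`` is reused by the
    chaotic-loss terms so the forward pass runs once per step.
    """
    O_layers, V_layers = forward_arrays(
        weight_mats, inputs, params, smooth=smooth, width=sg.width
    )
    loss, dL_dO = _loss_and_output_grad(O_layers[-1], targets, loss_kind)
    grads = backward_arrays(
        weight_mats, O_layers, V_layers, dL_dO, params, sg, reset_mode
    )
    return loss, grads, O_layers


def loss_bp_value(record: SpikeRecord, spec: LossSpec) -> float:
    """Task loss of a single recorded sample."""
    rates = rate_decode(record, record.n_layers)
    if spec.kind == "zero":
        return 0.0
    if spec.target.shape != rates.shape:
        raise ValueError(
            f"target shape {spec.target.shape} != output shape {rates.shape}"
        )
    if spec.kind == "mse_rate":
        return float(np.mean((rates - spec.target) ** 2))
    p = _softmax(rates)
    return float(-(spec.target * np.log(np.clip(p, 1e-300, None))).sum())


def backprop_bptt(
    weights: NetworkWeights,
    input_spikes: np.ndarray,
    params: LIFParams,
    loss: LossSpec,
    sg: SurrogateSpec,
    reset_mode: str = "constant",
    smooth: bool = False,
) -> list[np.ndarray]:
    """Gradient of the task loss for one sample, same shapes as weights.

    ``input_spikes`` may be ``(M_0, T)`` for a single sample or
    ``(B, M_0, T)`` for a batch (batch-mean loss).
    """
    input_spikes = np.asarray(input_spikes, dtype=float)
    if input_spikes.ndim == 2:
        inputs = input_spikes[None, :, :]
        targets = None if loss.target is None else loss.target[None, :]
    else:
        inputs = input_spikes
        targets = loss.target
    _, grads, _ = loss_and_grad_arrays(
        weights.weights,
        inputs,
        targets,
        params,
        sg,
        loss_kind=loss.kind,
        reset_mode=reset_mode,
        smooth=smooth,
    )
    return grads


def bp_update(
    weights: NetworkWeights, gradient: Sequence[np.ndarray], eta: float
) -> NetworkWeights:
    """Plain gradient-descent step ``w <- w - eta * g``."""
    if not eta > 0:
        raise ValueError("eta must be positive")
    if len(gradient) != len(weights.weights):
        raise ValueError("gradient/weight layer count mismatch")
    mats = []
    for w, g in zip(weights.weights, gradient):
        g = np.asarray(g, dtype=float)
        if g.shape != w.shape:
            raise ValueError(f"gradient shape {g.shape} != weight shape {w.shape}")
        mats.append(w - eta * g)
    return NetworkWeights(weights.layer_sizes, mats)


def export_gradients_csv(gradient: Sequence[np.ndarray], path: str) -> None:
    """Write gradients as rows (layer, row, col, value); col 0 = bias."""
    import pandas as pd

    rows = []
    for i, g in enumerate(gradient, start=1):
        for j in range(g.shape[0]):
            for k in range(g.shape[1]):
                rows.append((i, j + 1, k, g[j, k]))
    pd.DataFrame(rows, columns=["layer", "row", "col", "value"]).to_csv(
        path, index=False
    )
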