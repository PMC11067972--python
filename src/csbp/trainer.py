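"""Training loop combining task gradients with the annealed chaotic term.

One step of the map: forward-simulate the full batch, backpropagate the
task loss, add the analytic chaotic gradients on masked entries, apply
plain gradient descent, anneal ``z``.  With ``z = 0`` the step is
bit-for-bit a baseline gradient-descent step.  Full-batch data makes the
map deterministic, so the iteration ``W -> G(W)`` can be analyzed as a
discrete dynamical system (see :mod:`csbp.dynamics`).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chaos import ChaosConfig, anneal, chaos_terms_arrays
from .gradients import SurrogateSpec, loss_and_grad_arrays
from .lif import LIFParams, NetworkWeights

__all__ = [
    "Batch",
    "TrainState",
    "TrajectoryLog",
    "combine_gradients",
    "csbp_step",
    "train",
    "make_training_map",
]


@dataclasses.dataclass(frozen=True)
class Batch:
    """Full-batch task data: spike inputs ``(B, M_0, T)``, targets ``(B, n_out)``."""

    inputs: np.ndarray
    targets: np.ndarray | None


@dataclasses.dataclass
class TrainState:
    """Point of the training map: weights, chaos intensity, pseudo-time."""

    weights: NetworkWeights
    z: float
    m: int = 0
    eta: float = 0.1

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be nonnegative")
        if not self.eta > 0:
            raise ValueError("eta must be positive")


@dataclasses.dataclass
class TrajectoryLog:
    """Per-iteration training record plus the raw weight trajectory.

    ``frame`` columns: ``m``, ``z``, ``loss_bp``, ``loss_chaos`` and one
    ``w_{i}_{j}_{k}`` column per tracked weight.  ``weights_history`` has
    one flattened weight vector per iteration (epochs + 1 rows, the last
    being the final state).
    """

    frame: pd.DataFrame
    weights_history: np.ndarray
    final_weights: NetworkWeights
    seed: int | None = None

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def combine_gradients(
    grad_bp: Sequence[np.ndarray],
    chaos_terms: Sequence[np.ndarray] | None,
    mask_arrays: Sequence[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Task gradient plus chaotic gradient on masked entries.

    ``chaos_terms`` are already zero outside the mask (see
    :func:`csbp.chaos.chaos_terms_arrays`); passing ``None`` (the ``z = 0``
    degeneration) returns an exact copy of ``grad_bp``.
    """
    if chaos_terms is None:
        return [g.copy() for g in grad_bp]
    if len(chaos_terms) != len(grad_bp):
        raise ValueError("gradient/chaos layer count mismatch")
    out = []
    for i, (g, c) in enumerate(zip(grad_bp, chaos_terms)):
        if g.shape != c.shape:
            raise ValueError(f"layer {i + 1}: shape {c.shape} != {g.shape}")
        if mask_arrays is not None and np.any(c[~mask_arrays[i], :] != 0.0):
            raise ValueError(f"layer {i + 1}: chaos term leaks outside the mask")
        out.append(g + c)
    return out


def _step_arrays(
    weight_mats: list[np.ndarray],
    batch: Batch,
    z: float,
    eta: float,
    params: LIFParams,
    sg: SurrogateSpec,
    loss_kind: str,
    chaos: ChaosConfig,
    mask_arrays: Sequence[np.ndarray] | None,
) -> tuple[list[np.ndarray], float, float]:
    """One map application on raw weight matrices; returns losses too."""
    loss_bp, grad_bp, O_layers = loss_and_grad_arrays(
        weight_mats, batch.inputs, batch.targets, params, sg, loss_kind=loss_kind
    )
    if z == 0.0:
        combined = grad_bp
        loss_chaos = 0.0
    else:
        loss_chaos, chaos_grads = chaos_terms_arrays(
            weight_mats,
            O_layers,
            z,
            chaos.I0,
            mask_arrays=mask_arrays,
            include_bias=chaos.include_bias,
        )
        combined = [g + c for g, c in zip(grad_bp, chaos_grads)]
    new_mats = [w - eta * g for w, g in zip(weight_mats, combined)]
    for i, w in enumerate(new_mats):
        if not np.all(np.isfinite(w)):
            raise FloatingPointError(
                f"weight overflow in layer {i + 1} (z={z:.6g}, loss_bp={loss_bp:.6g})"
            )
    return new_mats, loss_bp, loss_chaos


def csbp_step(
    state: TrainState,
    batch: Batch,
    params: LIFParams,
    sg: SurrogateSpec,
    chaos: ChaosConfig,
    loss_kind: str = "mse_rate",
) -> TrainState:
    """One application of the training map ``G`` to ``state``.

    Weights move by ``-eta`` times the combined gradient, ``z`` is
    annealed (per-batch granularity; a full batch equals one batch here)
    and the pseudo-time ``m`` increments.
    """
    mask_arrays = chaos.mask_arrays(state.weights.layer_sizes)
    new_mats, _, _ = _step_arrays(
        state.weights.weights,
        batch,
        state.z,
        state.eta,
        params,
        sg,
        loss_kind,
        chaos,
        mask_arrays,
    )
    z_next = anneal(state.z, chaos.beta) if state.z > 0 else 0.0
    return TrainState(
        weights=NetworkWeights(state.weights.layer_sizes, new_mats),
        z=z_next,
        m=state.m + 1,
        eta=state.eta,
    )


def make_training_map(
    template: NetworkWeights,
    batch: Batch,
    z: float,
    eta: float,
    params: LIFParams,
    sg: SurrogateSpec,
    chaos: ChaosConfig,
    loss_kind: str = "mse_rate",
) -> Callable[[np.ndarray], np.ndarray]:
    """Frozen-``z`` training map on flattened weight vectors.

    Used by the dynamics module, where the annealing-driven
    nonautonomy is handled by freezing ``z`` per analysis window.
    """
    mask_arrays = chaos.mask_arrays(template.layer_sizes)
    shapes = [w.shape for w in template.weights]
    sizes = [w.size for w in template.weights]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def map_fn(vec: np.ndarray) -> np.ndarray:
        mats = [
            vec[offsets[i] : offsets[i + 1]].reshape(shapes[i])
            for i in range(len(shapes))
        ]
        new_mats, _, _ = _step_arrays(
            mats, batch, z, eta, params, sg, loss_kind, chaos, mask_arrays
        )
        return np.concatenate([w.ravel() for w in new_mats])

    return map_fn


def _resolve_task(task: str, layer_sizes, params, encoder, seed) -> Batch:
    from . import workbench

    if task == "xor":
        return workbench.xor_batch(params.T, encoder=encoder, seed=seed)
    if task == "regression":
        return workbench.regression_batch(
            layer_sizes, params.T, seed=seed
        )
    raise ValueError(f"unknown task {task!r} (expected 'xor' or 'regression')")


def train(
    task: str | Batch,
    net_spec: Sequence[int],
    lif_params: LIFParams,
    chaos_config: ChaosConfig,
    sg_spec: SurrogateSpec,
    epochs: int,
    seed: int | None = 0,
    eta: float = 0.1,
    loss_kind: str = "mse_rate",
    init_interval: tuple[float, float] = (-1.0, 1.0),
    track: Sequence[tuple[int, int, int]] = ((2, 2, 0),),
    encoder: str = "constant",
    init_weights: NetworkWeights | None = None,
) -> TrajectoryLog:
    """Full training run; one full-batch update per epoch.

    Weights initialize uniformly on ``init_interval`` from ``seed``
    unless ``init_weights`` is given.  The logged ``z`` column follows
    the closed form ``z0 * beta**m`` (exact geometric decay).  ``track``
    lists 1-based ``(layer, neuron, presyn)`` weight indices, presyn 0
    being the bias.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    layer_sizes = tuple(int(m) for m in net_spec)
    if isinstance(task, Batch):
        batch = task
    else:
        batch = _resolve_task(task, layer_sizes, lif_params, encoder, seed)
    if init_weights is not None:
        weights = init_weights.copy()
    else:
        low, high = init_interval
        weights = NetworkWeights.init_uniform(
            layer_sizes, low, high, rng=np.random.default_rng(seed)
        )
    mask_arrays = chaos_config.mask_arrays(layer_sizes)
    track = [tuple(map(int, t)) for t in track]
    for i, j, k in track:
        if not (1 <= i <= len(weights.weights)):
            raise ValueError(f"tracked weight layer {i} out of range")
        if not (1 <= j <= layer_sizes[i] and 0 <= k <= layer_sizes[i - 1]):
            raise ValueError(f"tracked weight ({i},{j},{k}) out of range")

    mats = [w.copy() for w in weights.weights]
    z0, beta = chaos_config.z0, chaos_config.beta
    n_params = weights.n_params
    history = np.empty((epochs + 1, n_params))
    rows = np.empty((epochs, 4 + len(track)))
    for m in range(epochs):
        z = z0 * beta**m if z0 > 0 else 0.0
        history[m] = np.concatenate([w.ravel() for w in mats])
        new_mats, loss_bp, loss_chaos = _step_arrays(
            mats, batch, z, eta, lif_params, sg_spec, loss_kind,
            chaos_config, mask_arrays,
        )
        rows[m, 0] = m
        rows[m, 1] = z
        rows[m, 2] = loss_bp
        rows[m, 3] = loss_chaos
        for c, (i, j, k) in enumerate(track):
            rows[m, 4 + c] = mats[i - 1][j - 1, k]
        mats = new_mats
    history[epochs] = np.concatenate([w.ravel() for w in mats])

    columns = ["m", "z", "loss_bp", "loss_chaos"] + [
        f"w_{i}_{j}_{k}" for i, j, k in track
    ]
    frame = pd.DataFrame(rows, columns=columns)
    frame["m"] = frame["m"].astype(int)
    return TrajectoryLog(
        frame=frame,
        weights_history=history,
        final_weights=NetworkWeights(layer_sizes, mats),
        seed=seed,
    )
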