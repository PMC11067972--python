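"""Task fixtures, run configuration, and desk-scale experiment drivers.

The XOR task is the primary fixture: 4 rows, constant spike encoding
(bit 1 fires every step), one-hot rate targets, full-batch updates so
one epoch equals one application of the training map.  A small sine
regression set exercises continuous targets through the same code
paths.  Experiment drivers pair chaotic runs against plain-BP baselines
(``z0 = 0``) over seed lists and summarize final-window losses,
accuracies and windowed Lyapunov exponents.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chaos import ChaosConfig
from .gradients import SurrogateSpec
from .lif import LIFParams, NetworkWeights, encode_constant, encode_poisson
from .trainer import Batch, TrajectoryLog, make_training_map, train
from .dynamics import LyapunovEstimate, windowed_lyapunov

__all__ = [
    "RunConfig",
    "ExperimentSummary",
    "xor_dataset",
    "xor_batch",
    "regression_dataset",
    "regression_batch",
    "final_window_mse",
    "xor_accuracy",
    "run_windowed_lyapunov",
    "run_fig2_experiment",
    "run_robustness_experiment",
]

FINAL_WINDOW = 500  # epochs averaged for the converged-loss statistic


def xor_dataset() -> list[tuple[np.ndarray, np.ndarray]]:
    """The 4 XOR rows with one-hot class targets (class 1 = "true")."""
    rows = [
        ((0, 0), (1.0, 0.0)),
        ((0, 1), (0.0, 1.0)),
        ((1, 0), (0.0, 1.0)),
        ((1, 1), (1.0, 0.0)),
    ]
    return [(np.array(x, dtype=float), np.array(y)) for x, y in rows]


def xor_batch(T: int, encoder: str = "constant", seed: int | None = None) -> Batch:
    """Spike-encoded full batch of the 4 XOR rows."""
    data = xor_dataset()
    if encoder == "constant":
        inputs = np.stack([encode_constant(x, T) for x, _ in data])
    elif encoder == "poisson":
        rng = np.random.default_rng(seed)
        inputs = np.stack([encode_poisson(x, T, rng) for x, _ in data])
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    targets = np.stack([y for _, y in data])
    return Batch(inputs=inputs, targets=targets)


def regression_dataset(
    n_points: int, seed: int | None = None, noise: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sine regression stand-in: ``y = sin(x)`` on a grid over [0, 2*pi]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.linspace(0.0, 2.0 * np.pi, n_points)
    y = np.sin(x)
    if noise > 0:
        y = y + noise * np.random.default_rng(seed).standard_normal(n_points)
    return x, y


def regression_batch(
    layer_sizes: Sequence[int],
    T: int,
    n_points: int = 16,
    seed: int | None = 0,
    noise: float = 0.0,
) -> Batch:
    """Poisson-encoded regression batch; targets are rates ``(y + 1) / 2``."""
    x, y = regression_dataset(n_points, seed=seed, noise=noise)
    rates = x / (2.0 * np.pi)
    rng = np.random.default_rng(seed)
    m0 = layer_sizes[0]
    inputs = np.stack(
        [encode_poisson(np.full(m0, r), T, rng) for r in rates]
    )
    targets = np.repeat(((y + 1.0) / 2.0)[:, None], layer_sizes[-1], axis=1)
    return Batch(inputs=inputs, targets=np.clip(targets, 0.0, 1.0))


@dataclasses.dataclass
class RunConfig:
    """Complete, serializable description of one training run."""

    task: str = "xor"
    arch: tuple[int, ...] = (2, 5, 2)
    lif: LIFParams = dataclasses.field(default_factory=LIFParams)
    surrogate: SurrogateSpec = dataclasses.field(default_factory=SurrogateSpec)
    loss_kind: str = "mse_rate"
    chaos: ChaosConfig = dataclasses.field(default_factory=ChaosConfig)
    eta: float = 1.0
    epochs: int = 10000
    seed: int = 0
    init_interval: tuple[float, float] = (-1.0, 1.0)
    track: tuple[tuple[int, int, int], ...] = ((2, 2, 0),)
    encoder: str = "constant"
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "arch": list(self.arch),
            "lif": dataclasses.asdict(self.lif),
            "surrogate": dataclasses.asdict(self.surrogate),
            "loss_kind": self.loss_kind,
            "chaos": {
                "z0": self.chaos.z0,
                "beta": self.chaos.beta,
                "I0": self.chaos.I0,
                "mask": None if self.chaos.mask is None
                else [list(p) for p in self.chaos.mask],
                "include_bias": self.chaos.include_bias,
                "anneal_granularity": self.chaos.anneal_granularity,
            },
            "eta": self.eta,
            "epochs": self.epochs,
            "seed": self.seed,
            "init_interval": list(self.init_interval),
            "track": [list(t) for t in self.track],
            "encoder": self.encoder,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        chaos = dict(d["chaos"])
        if chaos.get("mask") is not None:
            chaos["mask"] = tuple(tuple(p) for p in chaos["mask"])
        return cls(
            task=d["task"],
            arch=tuple(d["arch"]),
            lif=LIFParams(**d["lif"]),
            surrogate=SurrogateSpec(**d["surrogate"]),
            loss_kind=d["loss_kind"],
            chaos=ChaosConfig(**chaos),
            eta=d["eta"],
            epochs=d["epochs"],
            seed=d["seed"],
            init_interval=tuple(d["init_interval"]),
            track=tuple(tuple(t) for t in d["track"]),
            encoder=d["encoder"],
            out_dir=d.get("out_dir"),
        )

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        if os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(source))

    def run(self, init_weights: NetworkWeights | None = None) -> TrajectoryLog:
        return train(
            self.task,
            self.arch,
            self.lif,
            self.chaos,
            self.surrogate,
            self.epochs,
            seed=self.seed,
            eta=self.eta,
            loss_kind=self.loss_kind,
            init_interval=self.init_interval,
            track=self.track,
            encoder=self.encoder,
            init_weights=init_weights,
        )


@dataclasses.dataclass
class ExperimentSummary:
    """Paired chaotic-vs-baseline experiment outcome."""

    per_seed: pd.DataFrame
    lyapunov: pd.DataFrame | None
    config: RunConfig
    artifacts: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def median_mse(self) -> dict[str, float]:
        return {
            "csbp": float(self.per_seed["csbp_final_mse"].median()),
            "bp": float(self.per_seed["bp_final_mse"].median()),
        }

    @property
    def solved_counts(self) -> dict[str, int]:
        return {
            "csbp": int((self.per_seed["csbp_accuracy"] == 1.0).sum()),
            "bp": int((self.per_seed["bp_accuracy"] == 1.0).sum()),
        }


def final_window_mse(log: TrajectoryLog, window: int = FINAL_WINDOW) -> float:
    """Mean task loss over the last ``window`` logged epochs."""
    return float(log.frame["loss_bp"].iloc[-window:].mean())


def xor_accuracy(weights: NetworkWeights, lif: LIFParams,
                 encoder: str = "constant", seed: int | None = None) -> float:
    """Fraction of the 4 XOR rows classified correctly by argmax rate.

    ``np.argmax`` takes the first maximum, so rate ties resolve to
    class 0.
    """
    from .lif import forward_arrays

    batch = xor_batch(lif.T, encoder=encoder, seed=seed)
    O_layers, _ = forward_arrays(weights.weights, batch.inputs, lif)
    rates = O_layers[-1].mean(axis=2)
    pred = np.argmax(rates, axis=1)
    truth = np.argmax(batch.targets, axis=1)
    return float(np.mean(pred == truth))


def run_windowed_lyapunov(
    config: RunConfig,
    log: TrajectoryLog,
    window_len: int = 200,
    starts: Sequence[int] | None = None,
) -> list[LyapunovEstimate]:
    """Frozen-``z`` windowed Lyapunov exponents of a finished run."""
    batch = (
        xor_batch(config.lif.T, encoder=config.encoder, seed=config.seed)
        if config.task == "xor"
        else regression_batch(config.arch, config.lif.T, seed=config.seed)
    )
    template = log.final_weights

    def family(z, _x0):
        return make_training_map(
            template, batch, z, config.eta, config.lif, config.surrogate,
            config.chaos, loss_kind=config.loss_kind,
        )

    z_values = config.chaos.z0 * config.chaos.beta ** np.arange(
        len(log.weights_history)
    )
    return windowed_lyapunov(
        family, log.weights_history, z_values, window_len=window_len, starts=starts
    )


def _lyap_frame(estimates: list[LyapunovEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.window[0], e.window[1], e.z, e.lambda_max)
            for e in estimates
        ],
        columns=["start", "end", "z", "lambda_max"],
    )


def run_fig2_experiment(
    config: RunConfig | None = None,
    seeds: Sequence[int] = tuple(range(10)),
    out_dir: str | None = None,
    lyapunov_windows: bool = True,
    window_len: int = 200,
) -> ExperimentSummary:
    """Paired chaotic-vs-baseline XOR runs over a seed list.

    For every seed a chaotic run and a baseline run (``z0 = 0``) start
    from identical initial weights; the summary holds final-window
    losses, 4-row accuracies, and (for the first seed) windowed
    Lyapunov exponents at the start and end of the chaotic run.
    """
    config = config or RunConfig()
    rows = []
    artifacts: dict[str, str] = {}
    lyap = None
    for pos, seed in enumerate(seeds):
        cfg_c = dataclasses.replace(config, seed=seed)
        chaos_off = dataclasses.replace(config.chaos, z0=0.0)
        cfg_b = dataclasses.replace(config, seed=seed, chaos=chaos_off)
        log_c = cfg_c.run()
        log_b = cfg_b.run()
        rows.append(
            (
                seed,
                final_window_mse(log_c),
                final_window_mse(log_b),
                xor_accuracy(log_c.final_weights, config.lif),
                xor_accuracy(log_b.final_weights, config.lif),
            )
        )
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            for tag, log in (("csbp", log_c), ("bp", log_b)):
                path = os.path.join(out_dir, f"trajectory_{tag}_seed{seed}.csv")
                log.to_csv(path)
                artifacts[f"trajectory_{tag}_seed{seed}"] = path
        if pos == 0 and lyapunov_windows:
            n = config.epochs
            starts = sorted({0, n // 4, n // 2, 3 * n // 4, n - window_len})
            ests = run_windowed_lyapunov(
                cfg_c, log_c, window_len=window_len, starts=starts
            )
            lyap = _lyap_frame(ests)
            if out_dir:
                path = os.path.join(out_dir, "lyapunov_windows.csv")
                lyap.to_csv(path, index=False)
                artifacts["lyapunov_windows"] = path
    per_seed = pd.DataFrame(
        rows,
        columns=["seed", "csbp_final_mse", "bp_final_mse",
                 "csbp_accuracy", "bp_accuracy"],
    )
    if out_dir:
        path = os.path.join(out_dir, "summary.csv")
        per_seed.to_csv(path, index=False)
        artifacts["summary"] = path
    return ExperimentSummary(
        per_seed=per_seed, lyapunov=lyap, config=config, artifacts=artifacts
    )


def run_robustness_experiment(
    init_intervals: Sequence[tuple[float, float]] = (
        (-1.0, 1.0), (-2.0, 2.0), (-5.0, 5.0), (-10.0, 10.0),
    ),
    seeds: Sequence[int] = tuple(range(5)),
    config: RunConfig | None = None,
    out_dir: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Initial-interval robustness table for chaotic vs baseline training.

    Returns the per-cell table and a report with the across-interval
    spread (max - min of per-interval mean final loss) for both methods
    and the boolean "chaotic spread <= baseline spread".
    """
    config = config or RunConfig()
    rows = []
    for low, high in init_intervals:
        if high < low:
            raise ValueError(f"malformed interval ({low}, {high})")
        for seed in seeds:
            cfg_c = dataclasses.replace(
                config, seed=seed, init_interval=(low, high)
            )
            cfg_b = dataclasses.replace(
                cfg_c, chaos=dataclasses.replace(config.chaos, z0=0.0)
            )
            log_c = cfg_c.run()
            log_b = cfg_b.run()
            rows.append(
                (
                    low, high, seed,
                    final_window_mse(log_c), final_window_mse(log_b),
                    xor_accuracy(log_c.final_weights, config.lif),
                    xor_accuracy(log_b.final_weights, config.lif),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["low", "high", "seed", "csbp_final_mse", "bp_final_mse",
                 "csbp_accuracy", "bp_accuracy"],
    )
    means = table.groupby(["low", "high"])[["csbp_final_mse", "bp_final_mse"]].mean()
    spread_c = float(means["csbp_final_mse"].max() - means["csbp_final_mse"].min())
    spread_b = float(means["bp_final_mse"].max() - means["bp_final_mse"].min())
    report = {
        "csbp_spread": spread_c,
        "bp_spread": spread_b,
        "csbp_spread_leq_bp": bool(spread_c <= spread_b),
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "robustness.csv"), index=False)
    return table, report
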