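# csbp — chaotic spiking backpropagation

Surrogate-gradient training of leaky integrate-and-fire (LIF) spiking
networks with an annealed, neuron-intrinsic chaotic loss term, plus a
dynamical-systems toolbox for analyzing the resulting training map.

Each neuron contributes a cross-entropy-form loss
`-z * (I0*ln(h) + (1-I0)*ln(1-h))` on the sigmoid `h` of its
time-averaged drive.  Its analytic weight gradient, `-z*(I0-h)*s_k`,
enters the update as a plug-in term next to the ordinary
backpropagation-through-time gradient, and the intensity `z` is annealed
geometrically (`z <- beta*z`).  For large `z` the weight iteration is a
chaotic map (repelling fixed point, snap-back orbit, positive maximum
Lyapunov exponent); as `z` decays it degenerates exactly to plain
gradient descent.

## Layout

| module | contents |
|---|---|
| `csbp.lif` | LIF forward simulation, spike encoders/decoders, weight containers |
| `csbp.gradients` | surrogate specs, rate losses, BPTT, baseline update |
| `csbp.chaos` | chaotic loss, analytic gradient, annealing, logistic-map ablation |
| `csbp.trainer` | gradient combination, training step/loop, frozen-z training map |
| `csbp.dynamics` | Benettin Lyapunov estimator, windowed exponents, fixed-point/snap-back/bifurcation analysis |
| `csbp.workbench` | XOR / sine-regression fixtures, run configs, paired experiments |
| `csbp.cli` | `csbp` command-line entry point |

## CLI

```sh
# chaotic run on XOR ([2,5,2], z0=20, beta=0.9995) and a BP baseline
csbp train --task xor --arch 2,5,2 --z0 20 --beta 0.9995 --epochs 10000 \
           --seed 0 --track 2:2:0 --out runs/xor_csbp
csbp train --task xor --z0 0 --epochs 10000 --seed 0 --out runs/xor_bp

# windowed maximum Lyapunov exponents of a persisted run
csbp lyapunov --run runs/xor_csbp --window 200

# reduced scalar map analysis
csbp fixed-point --i0 0.65 --eta 1.0 --z 20
csbp bifurcation --z-max 150 --z-min 0.01 --points 400 --out bif.csv

# paired multi-seed experiments
csbp fig2 --seeds 10 --out runs/fig2
csbp robustness --seeds 5 --out runs/robustness
```

Run directories hold `trajectory.csv` (per-epoch `m`, `z`, losses,
tracked weights), `weights.json`, and a lossless `config.yaml` that
reruns bit-identically.

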