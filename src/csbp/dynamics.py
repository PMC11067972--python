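"""Dynamical-systems analysis of the training map.

Provides a Benettin two-trajectory estimator for the maximum Lyapunov
exponent, windowed exponents for annealed (nonautonomous) runs with the
chaos intensity frozen per window, a damped-Newton fixed-point locator
with Jacobian spectrum, a numerical snap-back-repeller search, and
bifurcation scans over the chaos intensity.

Reduced scalar maps of the form

    w' = w - eta * g_bp(w) + eta * z * (I0 - sigmoid(w * s)) * s

are provided for closed-form cross-checks: their fixed point solves
``sigmoid(w * s) = I0`` exactly when ``g_bp = 0``, i.e.
``w = ln(I0 / (1 - I0)) / s``, with map derivative
``1 - eta * z * s**2 * sigma'(w * s)`` there.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LyapunovEstimate",
    "FixedPointReport",
    "SnapbackReport",
    "max_lyapunov",
    "windowed_lyapunov",
    "find_fixed_point",
    "snapback_check",
    "bifurcation_scan",
    "chaos_scalar_map",
    "logistic_map",
    "theorem_fixed_point",
    "theorem_snapback_seed",
    "count_attractor_values",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def logistic_map(x: float) -> float:
    """Fully chaotic logistic map ``x' = 4 x (1 - x)``."""
    return 4.0 * x * (1.0 - x)


def chaos_scalar_map(
    z: float,
    eta: float = 1.0,
    I0: float = 0.65,
    s: float = 1.0,
    bp_gradient: Callable[[float], float] | None = None,
) -> Callable[[float], float]:
    """Reduced single-weight training map (see module docstring)."""

    def G(w):
        g = bp_gradient(w) if bp_gradient is not None else 0.0
        return w - eta * g + eta * z * (I0 - _sigmoid(w * s)) * s

    return G


def theorem_fixed_point(I0: float, epsilon: float = 1.0) -> float:
    """Predicted fixed point ``epsilon * ln(I0 / (1 - I0))``."""
    if not 0.0 < I0 < 1.0:
        raise ValueError("I0 must lie in (0, 1)")
    return epsilon * math.log(I0 / (1.0 - I0))


def theorem_snapback_seed(I0: float, epsilon: float = 1.0) -> float:
    """Predicted snap-back point; requires ``I0 != 0.5``."""
    if not 0.0 < I0 < 1.0:
        raise ValueError("I0 must lie in (0, 1)")
    if I0 == 0.5:
        raise ValueError("snap-back seed undefined at I0 = 0.5")
    if I0 > 0.5:
        return epsilon * math.log((2.0 * I0 - 1.0) / (2.0 - 2.0 * I0))
    return epsilon * math.log((2.0 * I0) / (1.0 - 2.0 * I0))


@dataclasses.dataclass
class LyapunovEstimate:
    """Maximum Lyapunov exponent over an iteration window (natural log)."""

    lambda_max: float
    window: tuple[int, int]
    delta0: float
    renorm_every: int = 1
    z: float | None = None


@dataclasses.dataclass
class FixedPointReport:
    """Located fixed point with Jacobian spectrum and prediction check."""

    w_bar: np.ndarray
    residual: float
    jacobian_spectrum: np.ndarray
    theorem_prediction: float | None = None
    prediction_error: float | None = None
    degenerate: bool = False
    converged: bool = True


@dataclasses.dataclass
class SnapbackReport:
    """Outcome of the numerical snap-back search.

    ``success=False`` means "not found", never a disproof.
    """

    w0: float | None
    steps: int
    closest_approach: float
    theorem_seed: float
    success: bool
    is_repeller: bool
    jacobian_mag: float


def _wrap_map(map_fn, x0):
    """Uniform vector interface for scalar or vector maps."""
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim == 0:
        return (lambda v: np.atleast_1d(float(map_fn(float(v[0]))))), x0.reshape(1), True
    return (lambda v: np.asarray(map_fn(v), dtype=float)), x0.copy(), False


def max_lyapunov(
    map_fn: Callable,
    x0,
    n_iter: int,
    delta0: float = 1e-8,
    n_discard: int = 0,
) -> LyapunovEstimate:
    """Benettin two-trajectory estimate of the maximum Lyapunov exponent.

    A reference and a perturbed trajectory evolve together; the
    separation is renormalized to ``delta0`` every step and
    ``lambda_max`` is the mean of ``ln(d_i / delta0)`` over the retained
    iterations.
    """
    if not delta0 > 0:
        raise ValueError("delta0 must be positive")
    if not n_iter > n_discard >= 0:
        raise ValueError("need n_iter > n_discard >= 0")
    fn, x, _ = _wrap_map(map_fn, x0)
    direction = np.ones_like(x) / math.sqrt(x.size)
    y = x + delta0 * direction
    total = 0.0
    count = 0
    for i in range(n_iter):
        x = fn(x)
        y = fn(y)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise FloatingPointError(f"orbit diverged at iteration {i}")
        diff = y - x
        d = float(np.linalg.norm(diff))
        if d == 0.0:
            d = 1e-300  # locally constant map: report strong contraction
            y = x + delta0 * direction
        else:
            y = x + diff * (delta0 / d)
        if i >= n_discard:
            total += math.log(d / delta0)
            count += 1
    return LyapunovEstimate(
        lambda_max=total / count,
        window=(n_discard, n_iter),
        delta0=delta0,
    )


def windowed_lyapunov(
    map_family: Callable[[float, np.ndarray], Callable],
    states: np.ndarray,
    z_values: Sequence[float],
    window_len: int = 200,
    stride: int | None = None,
    delta0: float = 1e-8,
    starts: Sequence[int] | None = None,
) -> list[LyapunovEstimate]:
    """Sliding-window exponents along a nonautonomous training run.

    ``map_family(z, x_start)`` must return the frozen-``z`` map;
    ``states[m]`` and ``z_values[m]`` are the visited state and chaos
    intensity at iteration ``m``.  Each window freezes ``z`` at its
    opening value and iterates the frozen map from the visited state.
    """
    states = np.asarray(states, dtype=float)
    n = len(states)
    if window_len < 50:
        raise ValueError("window_len must be >= 50")
    if window_len > n - 1:
        raise ValueError("window longer than trajectory")
    if starts is None:
        stride = stride or window_len
        starts = list(range(0, n - window_len, stride))
    out = []
    for start in starts:
        if start + window_len > n:
            raise ValueError(f"window at {start} exceeds trajectory length {n}")
        z = float(z_values[start])
        est = max_lyapunov(
            map_family(z, states[start]), states[start], window_len, delta0=delta0
        )
        est.window = (start, start + window_len)
        est.z = z
        out.append(est)
    return out


def _numjac(fn, x: np.ndarray, step: float = 1e-6, order: int = 2) -> np.ndarray:
    """Central-difference Jacobian; ``order=4`` for the reported spectrum."""
    n = x.size
    J = np.empty((n, n))
    for k in range(n):
        h = step * max(1.0, abs(x[k]))
        e = np.zeros(n)
        e[k] = 1.0
        if order == 2:
            J[:, k] = (fn(x + h * e) - fn(x - h * e)) / (2.0 * h)
        else:
            f1 = fn(x + h * e) - fn(x - h * e)
            f2 = fn(x + 2 * h * e) - fn(x - 2 * h * e)
            J[:, k] = (8.0 * f1 - f2) / (12.0 * h)
    return J


def find_fixed_point(
    map_fn: Callable,
    x_init,
    tol: float = 1e-10,
    max_iter: int = 200,
    I0: float | None = None,
    epsilon: float | None = None,
    jac_step: float = 1e-3,
) -> FixedPointReport:
    """Damped-Newton root of ``G(x) - x`` with Jacobian spectrum at the root.

    If the map is (numerically) the identity in a neighborhood of
    ``x_init`` the report is flagged ``degenerate`` — every point is
    fixed and no isolated root exists.  When ``I0`` (and optionally the
    scale ``epsilon``) are supplied, the closed-form prediction
    ``epsilon * ln(I0 / (1 - I0))`` and its error are reported.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    fn, x, scalar = _wrap_map(map_fn, x_init)
    F = lambda v: fn(v) - v

    # identity-map degeneracy probe
    probes = [x, x + 0.37, x - 1.21]
    if all(np.linalg.norm(F(p)) <= tol for p in probes):
        spectrum = np.abs(np.linalg.eigvals(_numjac(fn, x, order=4, step=jac_step)))
        return FixedPointReport(
            w_bar=float(x[0]) if scalar else x,
            residual=float(np.linalg.norm(F(x))),
            jacobian_spectrum=spectrum,
            degenerate=True,
        )

    res = float(np.linalg.norm(F(x)))
    converged = res <= tol
    for _ in range(max_iter):
        if res <= tol:
            converged = True
            break
        J = _numjac(F, x)
        try:
            dx = np.linalg.solve(J, -F(x))
        except np.linalg.LinAlgError:
            dx = -np.linalg.pinv(J) @ F(x)
        alpha = 1.0
        while alpha > 1e-6:
            x_new = x + alpha * dx
            res_new = float(np.linalg.norm(F(x_new)))
            if res_new < res:
                x, res = x_new, res_new
                break
            alpha *= 0.5
        else:
            break  # no descent direction left
    J_G = _numjac(fn, x, order=4, step=jac_step)
    spectrum = np.abs(np.linalg.eigvals(J_G))
    prediction = prediction_error = None
    if I0 is not None:
        prediction = theorem_fixed_point(I0, 1.0 if epsilon is None else epsilon)
        prediction_error = float(np.max(np.abs(x - prediction)))
    return FixedPointReport(
        w_bar=float(x[0]) if scalar else x,
        residual=res,
        jacobian_spectrum=spectrum,
        theorem_prediction=prediction,
        prediction_error=prediction_error,
        converged=converged,
    )


def snapback_check(
    map_fn: Callable[[float], float],
    w_bar: float,
    I0: float,
    search_radius: float = 2.0,
    max_steps: int = 6,
    tol: float = 1e-8,
    epsilon: float = 1.0,
    grid_points: int = 4001,
) -> SnapbackReport:
    """Numerical snap-back search for a scalar map.

    Seeds at the closed-form snap-back prediction, then root-finds
    points whose ``p``-step forward image lands on ``w_bar``
    (``p = 1..max_steps``), excluding the fixed point itself.  Requires
    the fixed point to be repelling (|G'| > 1); otherwise the
    prerequisite failure is reported.  Failure to find an orbit is
    reported as not-found, never as disproof.
    """
    from scipy.optimize import brentq

    if I0 == 0.5:
        raise ValueError("snap-back analysis requires I0 != 0.5")
    w_bar = float(w_bar)
    h = 1e-5
    jac = abs(
        (8 * (map_fn(w_bar + h) - map_fn(w_bar - h))
         - (map_fn(w_bar + 2 * h) - map_fn(w_bar - 2 * h))) / (12 * h)
    )
    seed = theorem_snapback_seed(I0, epsilon)
    if jac <= 1.0:
        return SnapbackReport(
            w0=None, steps=0, closest_approach=float("inf"),
            theorem_seed=seed, success=False, is_repeller=False, jacobian_mag=jac,
        )

    grid = np.linspace(seed - search_radius, seed + search_radius, grid_points)

    def iterate(w: float, p: int) -> float:
        for _ in range(p):
            w = map_fn(w)
        return w

    best = (None, 0, float("inf"))
    for p in range(1, max_steps + 1):
        vals = np.array([iterate(w, p) - w_bar for w in grid])
        finite = np.isfinite(vals)
        roots = []
        for a in range(len(grid) - 1):
            if not (finite[a] and finite[a + 1]):
                continue
            if vals[a] == 0.0:
                roots.append(grid[a])
            elif vals[a] * vals[a + 1] < 0:
                roots.append(
                    brentq(lambda w: iterate(w, p) - w_bar, grid[a], grid[a + 1],
                           xtol=1e-14)
                )
        roots = [r for r in roots if abs(r - w_bar) > 1e-6]
        if roots:
            w0 = min(roots, key=lambda r: abs(r - seed))
            approach = abs(iterate(w0, p) - w_bar)
            if approach < best[2]:
                best = (w0, p, approach)
            if approach <= tol:
                return SnapbackReport(
                    w0=w0, steps=p, closest_approach=approach,
                    theorem_seed=seed, success=True, is_repeller=True,
                    jacobian_mag=jac,
                )
    return SnapbackReport(
        w0=best[0], steps=best[1], closest_approach=best[2],
        theorem_seed=seed, success=False, is_repeller=True, jacobian_mag=jac,
    )


def bifurcation_scan(
    map_fn_family: Callable[[float], Callable[[float], float]],
    z_grid: Sequence[float],
    n_transient: int = 500,
    n_sample: int = 100,
    x0: float = 0.0,
    carry_state: bool = True,
) -> pd.DataFrame:
    """Sampled attractor values over a descending grid of chaos intensities.

    For each frozen ``z``, iterate the scalar map, discard transients,
    record ``n_sample`` values.  With ``carry_state`` the final state of
    one ``z`` seeds the next (standard continuation sweep).  Returns a
    frame with columns ``z``, ``sample_index``, ``value``.
    """
    z_grid = list(z_grid)
    if any(z < 0 for z in z_grid):
        raise ValueError("z grid must be nonnegative")
    if any(b > a for a, b in zip(z_grid, z_grid[1:])) and len(z_grid) > 1:
        raise ValueError("z grid must be descending")
    if n_transient < 1 or n_sample < 1:
        raise ValueError("n_transient and n_sample must be >= 1")
    rows = []
    x = float(x0)
    for z in z_grid:
        G = map_fn_family(z)
        if not carry_state:
            x = float(x0)
        for _ in range(n_transient):
            x = G(x)
            if not math.isfinite(x):
                raise FloatingPointError(f"non-finite orbit at z={z}")
        for idx in range(n_sample):
            x = G(x)
            if not math.isfinite(x):
                raise FloatingPointError(f"non-finite orbit at z={z}")
            rows.append((z, idx, x))
    return pd.DataFrame(rows, columns=["z", "sample_index", "value"])


def count_attractor_values(values: Sequence[float], tol: float = 1e-4) -> int:
    """Number of distinct attractor samples after clustering at ``tol``."""
    return len(np.unique(np.round(np.asarray(values, dtype=float) / tol)))
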