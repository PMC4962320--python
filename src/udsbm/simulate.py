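"""Stochastic trajectory generation for (underdamped) scaled Brownian motion.

The underdamped update is the explicit Euler-Maruyama scheme with
coefficients frozen at the left endpoint of each step,

    v_{i+1} = v_i - gamma(t_i) v_i dt + gamma(t_i) sqrt(2 D(t_i) dt) zeta_i,
    x_{i+1} = x_i + v_i dt,

with zeta_i standard normal.  The noise amplitude gamma sqrt(2 D), i.e.
sqrt(2 gamma T / m), is fixed by requiring the stationary velocity variance
T/m in the frozen-coefficient limit (fluctuation-dissipation).  The
overdamped counterpart drops the velocity,

    x_{i+1} = x_i + sqrt(2 D(t_i) dt) zeta_i.

All trajectories of an ensemble advance in lockstep, one normal draw per
step and trajectory from a single seeded generator, so runs are bit
reproducible for a given (params, dt, seed).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .containers import TrajectoryEnsemble
from .model import ModelParams, damping, diffusivity

__all__ = ["recommend_dt", "simulate_udsbm", "simulate_sbm", "sample_indices"]

#: hard stability bound for the explicit scheme, in units of 1/gamma0
_DT_STABILITY_FACTOR = 0.1


def recommend_dt(params: ModelParams, t_max: Optional[float] = None) -> float:
    """Heuristic step: resolve both the velocity relaxation (0.01/gamma0)
    and the coefficient variation (0.01 tau0)."""
    return min(0.01 / params.gamma0, 0.01 * params.tau0)


def sample_indices(
    n_steps: int, thinning: Union[int, str] = 1, points_per_decade: int = 32
) -> np.ndarray:
    """Step indices to store.

    ``thinning`` is either an integer stride (1 keeps every step) or
    ``"log"`` for a logarithmically thinned grid with roughly
    ``points_per_decade`` samples per decade, which emulates long-time
    figures at a fraction of the memory.
    """
    if thinning == "log":
        idx = np.unique(
            np.round(
                np.geomspace(1, n_steps, max(2, int(points_per_decade * np.log10(n_steps) + 1)))
            ).astype(np.int64)
        )
        return np.concatenate(([0], idx))
    stride = int(thinning)
    if stride < 1:
        raise ValueError("thinning stride must be >= 1")
    idx = np.arange(0, n_steps + 1, stride, dtype=np.int64)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx


def _check_dt(params: ModelParams, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be positive")
    limit = _DT_STABILITY_FACTOR / params.gamma0
    if dt > limit * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt:g} exceeds the stability bound {limit:g} = 0.1/gamma0; "
            f"recommended dt = {recommend_dt(params):g}"
        )


def simulate_udsbm(
    params: ModelParams,
    dt: float,
    n_steps: int,
    n_traj: int,
    seed: int,
    thinning: Union[int, str] = 1,
    v0: Union[str, float] = "thermal",
    store_velocities: bool = False,
    noise: bool = True,
) -> TrajectoryEnsemble:
    """Simulate an ensemble of underdamped trajectories.

    ``v0="thermal"`` draws initial velocities from N(0, T0/m); a float sets
    a common deterministic initial velocity (used with ``noise=False`` to
    test the pure relaxation x(t) = (v0/gamma0)(1 - e^{-gamma0 t}) for
    alpha = 1).  x(0) = 0 always.
    """
    _check_dt(params, dt)
    if n_steps < 1 or n_traj < 1:
        raise ValueError("n_steps and n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    idx = sample_indices(n_steps, thinning)
    times_grid = idx * dt

    t_steps = np.arange(n_steps) * dt
    g = damping(params, t_steps)
    gdt = g * dt
    amp = g * np.sqrt(2.0 * diffusivity(params, t_steps) * dt) if noise else np.zeros(n_steps)

    if v0 == "thermal":
        v = rng.normal(0.0, np.sqrt(params.T0 / params.m), size=n_traj)
    else:
        v = np.full(n_traj, float(v0))
    x = np.zeros(n_traj)

    positions = np.empty((n_traj, idx.size))
    velocities = np.empty((n_traj, idx.size)) if store_velocities else None
    store_map = {int(i): k for k, i in enumerate(idx)}
    if 0 in store_map:
        positions[:, 0] = x
        if store_velocities:
            velocities[:, 0] = v

    check_every = 10_000
    for i in range(n_steps):
        x = x + v * dt
        if noise:
            v = v - gdt[i] * v + amp[i] * rng.standard_normal(n_traj)
        else:
            v = v - gdt[i] * v
        k = store_map.get(i + 1)
        if k is not None:
            positions[:, k] = x
            if store_velocities:
                velocities[:, k] = v
        if (i + 1) % check_every == 0 and not np.isfinite(x[0]):
            raise FloatingPointError(f"non-finite state at step {i + 1}")
    if not (np.isfinite(positions[:, -1]).all() and np.isfinite(v).all()):
        raise FloatingPointError(f"non-finite state at step {n_steps}")

    return TrajectoryEnsemble(
        times=times_grid,
        positions=positions,
        velocities=velocities,
        dt=dt,
        seed=seed,
        params=params,
        scheme_tag="euler-maruyama-udsbm",
    )


def simulate_sbm(
    params: ModelParams,
    dt: float,
    n_steps: int,
    n_traj: int,
    seed: int,
    thinning: Union[int, str] = 1,
    noise: bool = True,
) -> TrajectoryEnsemble:
    """Simulate overdamped scaled Brownian motion (no velocities stored)."""
    _check_dt(params, dt)
    if n_steps < 1 or n_traj < 1:
        raise ValueError("n_steps and n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    idx = sample_indices(n_steps, thinning)
    times_grid = idx * dt

    t_steps = np.arange(n_steps) * dt
    amp = np.sqrt(2.0 * diffusivity(params, t_steps) * dt) if noise else np.zeros(n_steps)

    x = np.zeros(n_traj)
    positions = np.empty((n_traj, idx.size))
    store_map = {int(i): k for k, i in enumerate(idx)}
    if 0 in store_map:
        positions[:, 0] = x
    for i in range(n_steps):
        x = x + amp[i] * rng.standard_normal(n_traj)
        k = store_map.get(i + 1)
        if k is not None:
            positions[:, k] = x
    if not np.isfinite(positions[:, -1]).all():
        raise FloatingPointError(f"non-finite state at step {n_steps}")

    return TrajectoryEnsemble(
        times=times_grid,
        positions=positions,
        velocities=None,
        dt=dt,
        seed=seed,
        params=params,
        scheme_tag="euler-maruyama-sbm",
    )
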