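"""Estimators turning trajectory ensembles into MSD, time-averaged MSD and
velocity-correlation curves, plus ergodicity/ageing diagnostics.

Conventions
-----------
* The time-averaged MSD uses all overlapping windows (the maximal
  estimator, the Riemann sum of the defining integral); lags must lie on
  the sampling grid, no interpolation is performed.
* Uncertainties on ensemble-averaged quantities are across-trajectory
  standard errors; the autocorrelated within-trajectory error of a single
  time average is not modelled.
* For d-dimensional trajectories (granular-gas tracers) displacements are
  summed over axes; ``per_axis=True`` divides by d, which is how 3D gas
  moments are compared with the 1D Langevin theory.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np

from .containers import EBReport, RegimeReport, StatCurve, Trajectory, TrajectoryEnsemble, classify_slope

__all__ = [
    "ensemble_msd",
    "time_averaged_msd",
    "ensemble_tamsd",
    "vcf_estimator",
    "local_slope",
    "eb_diagnostics",
]


def _positions_3d(positions: np.ndarray) -> np.ndarray:
    """Normalise to shape (N, n, d)."""
    if positions.ndim == 2:
        return positions[:, :, None]
    return positions


def _sq_disp(positions: np.ndarray, per_axis: bool) -> np.ndarray:
    """Squared displacement from the initial point, shape (N, n)."""
    p = _positions_3d(positions)
    d2 = ((p - p[:, :1, :]) ** 2).sum(axis=2)
    if per_axis:
        d2 = d2 / p.shape[2]
    return d2


def ensemble_msd(
    ensemble: TrajectoryEnsemble,
    times: Optional[Sequence[float]] = None,
    per_axis: bool = False,
) -> StatCurve:
    """Ensemble MSD <x^2(t)> with the initial position subtracted.

    ``times`` restricts the curve to a subset of the sampling grid (values
    must match grid points exactly).  Standard errors are sample SD / sqrt(N).
    """
    if ensemble.n_traj < 2:
        raise ValueError("ensemble MSD needs at least 2 trajectories")
    d2 = _sq_disp(ensemble.positions, per_axis)
    grid = ensemble.times
    if times is not None:
        sel = _grid_indices(grid, np.asarray(times, dtype=float), "time")
        grid = grid[sel]
        d2 = d2[:, sel]
    mean = d2.mean(axis=0)
    stderr = d2.std(axis=0, ddof=1) / np.sqrt(ensemble.n_traj)
    keep = grid > 0 if grid[0] == 0.0 else slice(None)
    # t = 0 gives a trivial zero with zero error; keep it, it is well defined
    return StatCurve(
        abscissa=grid,
        values=mean,
        stderr=stderr,
        kind="msd",
        model_tag="empirical",
        params=ensemble.params,
    )


def _uniform_step(times: np.ndarray) -> float:
    steps = np.diff(times)
    if steps.size == 0:
        raise ValueError("need at least two samples")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-8, atol=0):
        raise ValueError("time-averaged estimators need a uniform sampling grid")
    return float(dt)


def _lag_steps(times: np.ndarray, lags: np.ndarray) -> np.ndarray:
    dt = _uniform_step(times)
    k = np.round(np.asarray(lags, dtype=float) / dt).astype(int)
    if np.any(np.abs(k * dt - lags) > 1e-8 * dt + 1e-12):
        bad = lags[np.abs(k * dt - lags) > 1e-8 * dt + 1e-12]
        raise ValueError(
            f"lags {bad} are not multiples of the sampling step {dt:g}; "
            "interpolation is refused, snap lags to the grid"
        )
    if np.any(k < 1) or np.any(k >= times.size):
        raise ValueError("lags must satisfy 0 < lag < measurement time")
    return k


def _grid_indices(grid: np.ndarray, values: np.ndarray, what: str) -> np.ndarray:
    idx = np.searchsorted(grid, values)
    idx = np.clip(idx, 0, grid.size - 1)
    left = np.clip(idx - 1, 0, grid.size - 1)
    idx = np.where(np.abs(grid[left] - values) < np.abs(grid[idx] - values), left, idx)
    tol = 1e-8 * max(1.0, float(np.abs(grid).max()))
    if np.any(np.abs(grid[idx] - values) > tol):
        raise ValueError(f"{what} values must lie on the sampling grid")
    return idx


def _tamsd_matrix(positions: np.ndarray, ks: np.ndarray, per_axis: bool) -> np.ndarray:
    """Per-trajectory time-averaged MSD, shape (N, len(ks))."""
    p = _positions_3d(positions)
    out = np.empty((p.shape[0], ks.size))
    for j, k in enumerate(ks):
        inc = p[:, k:, :] - p[:, :-k, :]
        out[:, j] = (inc**2).sum(axis=2).mean(axis=1)
    if per_axis:
        out /= p.shape[2]
    return out


def time_averaged_msd(
    traj: Union[Trajectory, TrajectoryEnsemble],
    lags: Sequence[float],
    per_axis: bool = False,
) -> StatCurve:
    """Time-averaged MSD of a single trajectory.

    delta^2(lag) = mean over the n - k overlapping windows of
    [x(t'+lag) - x(t')]^2, with k = lag/dt.
    """
    if isinstance(traj, TrajectoryEnsemble):
        if traj.n_traj != 1:
            raise ValueError("time_averaged_msd takes a single trajectory")
        traj = traj[0]
    lags = np.asarray(lags, dtype=float)
    ks = _lag_steps(traj.times, lags)
    vals = _tamsd_matrix(traj.positions[None, ...], ks, per_axis)[0]
    return StatCurve(
        abscissa=lags,
        values=vals,
        kind="tamsd",
        model_tag="empirical",
        measurement_time=float(traj.times[-1]),
        params=traj.params,
    )


def ensemble_tamsd(
    ensemble: TrajectoryEnsemble,
    lags: Sequence[float],
    per_axis: bool = False,
) -> StatCurve:
    """Mean over per-trajectory time-averaged MSDs, with across-trajectory
    standard errors."""
    lags = np.asarray(lags, dtype=float)
    ks = _lag_steps(ensemble.times, lags)
    mat = _tamsd_matrix(ensemble.positions, ks, per_axis)
    stderr = (
        mat.std(axis=0, ddof=1) / np.sqrt(ensemble.n_traj) if ensemble.n_traj > 1 else None
    )
    return StatCurve(
        abscissa=lags,
        values=mat.mean(axis=0),
        stderr=stderr,
        kind="tamsd",
        model_tag="empirical",
        measurement_time=ensemble.measurement_time,
        params=ensemble.params,
    )


def vcf_estimator(
    ensemble: TrajectoryEnsemble,
    t1: float,
    lags: Sequence[float],
    per_axis: bool = False,
) -> StatCurve:
    """Empirical velocity correlation <v(t1) v(t1+lag)> over trajectories.

    Requires stored velocities; t1 and t1+lag must lie on the sampling
    grid.  A lag of 0 estimates the velocity variance, which should track
    the bath temperature T(t1)/m.
    """
    if ensemble.velocities is None:
        raise ValueError("velocity correlation needs stored velocities")
    lags = np.asarray(lags, dtype=float)
    grid = ensemble.times
    i1 = int(_grid_indices(grid, np.array([t1], dtype=float), "t1")[0])
    i2 = _grid_indices(grid, grid[i1] + lags, "lag")
    v = _positions_3d(ensemble.velocities)
    prod = (v[:, i1, None, :] * v[:, i2, :]).sum(axis=2)
    if per_axis:
        prod = prod / v.shape[2]
    stderr = (
        prod.std(axis=0, ddof=1) / np.sqrt(ensemble.n_traj) if ensemble.n_traj > 1 else None
    )
    # report at strictly increasing abscissa; lag 0 is allowed
    order = np.argsort(lags)
    return StatCurve(
        abscissa=lags[order],
        values=prod.mean(axis=0)[order],
        stderr=None if stderr is None else stderr[order],
        kind="vcf",
        model_tag="empirical",
        params=ensemble.params,
    )


def local_slope(
    curve: StatCurve,
    window_decades: float = 0.5,
    n_windows: int = 20,
    min_points: int = 5,
) -> RegimeReport:
    """Sliding-window log-log slopes of a positive curve.

    Each window spans ``window_decades`` in the abscissa; windows with
    fewer than ``min_points`` strictly positive values are skipped with a
    warning.
    """
    x, y = curve.abscissa, curve.values
    pos = (x > 0) & (y > 0)
    if pos.sum() < curve.values.size:
        warnings.warn("nonpositive values skipped in local_slope", stacklevel=2)
    lx, ly = np.log10(x[pos]), np.log10(y[pos])
    if lx.size < min_points:
        raise ValueError(f"need at least {min_points} positive points")
    centers = np.linspace(lx[0] + window_decades / 2, lx[-1] - window_decades / 2, n_windows)
    windows, slopes, labels = [], [], []
    alpha = curve.params.alpha if curve.params is not None else None
    for c in centers:
        sel = (lx >= c - window_decades / 2) & (lx <= c + window_decades / 2)
        if sel.sum() < min_points:
            continue
        slope = float(np.polyfit(lx[sel], ly[sel], 1)[0])
        windows.append((10 ** (c - window_decades / 2), 10 ** (c + window_decades / 2)))
        slopes.append(slope)
        labels.append(classify_slope(slope, alpha))
    crossovers = {}
    if curve.params is not None:
        crossovers["1/gamma0"] = 1.0 / curve.params.gamma0
        if curve.params.alpha != 1.0:
            crossovers["tau0"] = curve.params.tau0
        crossovers = dict(sorted(crossovers.items(), key=lambda kv: kv[1]))
    return RegimeReport(crossover_times=crossovers, windows=windows, slopes=slopes, labels=labels)


def eb_diagnostics(
    ensemble: TrajectoryEnsemble,
    lags: Sequence[float],
    truncation_fractions: Sequence[float] = (0.25, 0.5, 1.0),
    per_axis: bool = False,
) -> EBReport:
    """Weak ergodicity breaking and ageing diagnostics.

    ``ratio`` compares the ensemble-averaged TAMSD with the ensemble MSD at
    matched (lag) times: unity for an ergodic process, below unity for the
    ageing subdiffusive protocols.  The ageing exponent is the slope of
    log TAMSD versus log measurement time at fixed lag, obtained by
    truncating the trajectories at ``truncation_fractions`` of their
    length; scaled Brownian motion predicts alpha - 1.
    """
    lags = np.asarray(lags, dtype=float)
    tamsd_curve = ensemble_tamsd(ensemble, lags, per_axis)
    msd_curve = ensemble_msd(ensemble, times=lags, per_axis=per_axis)
    ratio = tamsd_curve.values / msd_curve.values
    if tamsd_curve.stderr is not None:
        rel = np.sqrt(
            (tamsd_curve.stderr / tamsd_curve.values) ** 2
            + (msd_curve.stderr / np.maximum(msd_curve.values, 1e-300)) ** 2
        )
        ratio_stderr = ratio * rel
    else:
        ratio_stderr = None

    ageing = None
    fracs = sorted(set(float(f) for f in truncation_fractions))
    if len(fracs) >= 2:
        fixed_lag = lags[0]
        ts, vals = [], []
        n = ensemble.times.size
        for f in fracs:
            stop = max(int(round(n * f)), 2)
            sub = TrajectoryEnsemble(
                times=ensemble.times[:stop],
                positions=ensemble.positions[:, :stop],
                velocities=None,
                dt=ensemble.dt,
                seed=ensemble.seed,
                params=ensemble.params,
                scheme_tag=ensemble.scheme_tag,
            )
            if fixed_lag >= sub.times[-1]:
                continue
            c = ensemble_tamsd(sub, [fixed_lag], per_axis)
            ts.append(sub.times[-1])
            vals.append(c.values[0])
        if len(ts) >= 2 and np.all(np.asarray(vals) > 0):
            ageing = float(np.polyfit(np.log(ts), np.log(vals), 1)[0])
    return EBReport(lags=lags, ratio=ratio, ratio_stderr=ratio_stderr, ageing_exponent=ageing)
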