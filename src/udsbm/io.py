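"""Plain-text file formats: parameter configs, statistic curves and
trajectory ensembles.

Everything is delimited text with ``#`` comment headers so that runs remain
human-readable and diffable; floats are written with ``repr`` precision and
round-trip exactly.  Parameter files are flat ``key = value`` pairs with
keys T0, gamma0, m, tau0, alpha — the derived D0 and nu are never read.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np

from .containers import StatCurve, Trajectory, TrajectoryEnsemble
from .model import ModelParams

__all__ = [
    "read_params",
    "write_params",
    "read_curve",
    "write_curve",
    "read_trajectory",
    "write_trajectory",
    "read_ensemble",
    "write_ensemble",
    "read_spt_table",
]


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# parameter configs


def write_params(params: ModelParams, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write("# thermal-protocol parameters (kB = 1); D0 and nu are derived\n")
        for k, v in params.to_dict().items():
            fh.write(f"{k} = {_fmt(v)}\n")


def read_params(path: Union[str, os.PathLike]) -> ModelParams:
    d: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            d[k] = float(v)
    return ModelParams.from_dict(d)


def _params_header(params: Optional[ModelParams]) -> list[str]:
    if params is None:
        return []
    return [f"# param {k} = {_fmt(v)}" for k, v in params.to_dict().items()]


def _parse_header(path) -> tuple[dict[str, str], dict[str, float], list[str]]:
    meta: dict[str, str] = {}
    pdict: dict[str, float] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("param ") and "=" in body:
                    k, v = body[len("param "):].split("=", 1)
                    pdict[k.strip()] = float(v)
                elif "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            elif line.strip():
                rows.append(line)
    return meta, pdict, rows


# ---------------------------------------------------------------------------
# statistic curves


def write_curve(curve: StatCurve, path: Union[str, os.PathLike]) -> None:
    cols = ["abscissa", "value"] + (["stderr"] if curve.stderr is not None else [])
    with open(path, "w") as fh:
        fh.write(f"# kind = {curve.kind}\n")
        fh.write(f"# model_tag = {curve.model_tag}\n")
        if curve.measurement_time is not None:
            fh.write(f"# measurement_time = {_fmt(curve.measurement_time)}\n")
        for line in _params_header(curve.params):
            fh.write(line + "\n")
        fh.write(f"# columns = {' '.join(cols)}\n")
        for i in range(len(curve)):
            row = [_fmt(curve.abscissa[i]), _fmt(curve.values[i])]
            if curve.stderr is not None:
                row.append(_fmt(curve.stderr[i]))
            fh.write("\t".join(row) + "\n")


def read_curve(path: Union[str, os.PathLike]) -> StatCurve:
    meta, pdict, rows = _parse_header(path)
    data = np.array([[float(x) for x in r.split()] for r in rows])
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 data columns")
    mt = meta.get("measurement_time")
    return StatCurve(
        abscissa=data[:, 0],
        values=data[:, 1],
        stderr=data[:, 2] if data.shape[1] == 3 else None,
        kind=meta.get("kind", "msd"),
        model_tag=meta.get("model_tag", "empirical"),
        measurement_time=None if mt is None else float(mt),
        params=ModelParams.from_dict(pdict) if pdict else None,
    )


# ---------------------------------------------------------------------------
# trajectories and ensembles


_AXES = ("x", "y", "z")


def write_trajectory(traj: Trajectory, path: Union[str, os.PathLike]) -> None:
    d = traj.ndim_space
    pos = traj.positions.reshape(len(traj.times), d)
    vel = None if traj.velocities is None else traj.velocities.reshape(len(traj.times), d)
    cols = ["time"] + list(_AXES[:d])
    if vel is not None:
        cols += [f"v{a}" for a in _AXES[:d]]
    with open(path, "w") as fh:
        if traj.dt is not None:
            fh.write(f"# dt = {_fmt(traj.dt)}\n")
        if traj.seed is not None:
            fh.write(f"# seed = {traj.seed}\n")
        fh.write(f"# scheme_tag = {traj.scheme_tag}\n")
        for line in _params_header(traj.params):
            fh.write(line + "\n")
        fh.write(f"# columns = {' '.join(cols)}\n")
        for i, t in enumerate(traj.times):
            row = [_fmt(t)] + [_fmt(v) for v in pos[i]]
            if vel is not None:
                row += [_fmt(v) for v in vel[i]]
            fh.write("\t".join(row) + "\n")


def read_trajectory(path: Union[str, os.PathLike]) -> Trajectory:
    meta, pdict, rows = _parse_header(path)
    cols = meta.get("columns", "time x").split()
    data = np.array([[float(x) for x in r.split()] for r in rows])
    d = sum(1 for c in cols if c in _AXES)
    has_vel = any(c.startswith("v") for c in cols[1:])
    pos = data[:, 1 : 1 + d]
    vel = data[:, 1 + d : 1 + 2 * d] if has_vel else None
    if d == 1:
        pos = pos[:, 0]
        vel = None if vel is None else vel[:, 0]
    dt = meta.get("dt")
    seed = meta.get("seed")
    return Trajectory(
        times=data[:, 0],
        positions=pos,
        velocities=vel,
        dt=None if dt is None else float(dt),
        seed=None if seed is None else int(seed),
        params=ModelParams.from_dict(pdict) if pdict else None,
        scheme_tag=meta.get("scheme_tag", "unknown"),
    )


def write_ensemble(ensemble: TrajectoryEnsemble, directory: Union[str, os.PathLike]) -> None:
    """One file per trajectory plus a manifest recording shared metadata."""
    os.makedirs(directory, exist_ok=True)
    names = [f"traj_{i:05d}.txt" for i in range(ensemble.n_traj)]
    with open(os.path.join(directory, "manifest.txt"), "w") as fh:
        fh.write(f"# n_traj = {ensemble.n_traj}\n")
        if ensemble.dt is not None:
            fh.write(f"# dt = {_fmt(ensemble.dt)}\n")
        if ensemble.seed is not None:
            fh.write(f"# seed = {ensemble.seed}\n")
        fh.write(f"# scheme_tag = {ensemble.scheme_tag}\n")
        for line in _params_header(ensemble.params):
            fh.write(line + "\n")
        for name in names:
            fh.write(name + "\n")
    for i, name in enumerate(names):
        write_trajectory(ensemble[i], os.path.join(directory, name))


def read_ensemble(directory: Union[str, os.PathLike]) -> TrajectoryEnsemble:
    manifest = os.path.join(directory, "manifest.txt")
    meta, pdict, rows = _parse_header(manifest)
    trajs = [read_trajectory(os.path.join(directory, name)) for name in rows]
    if not trajs:
        raise ValueError(f"{manifest}: no trajectories listed")
    times = trajs[0].times
    for tr in trajs[1:]:
        if not np.array_equal(tr.times, times):
            raise ValueError("ensemble trajectories must share one time grid")
    positions = np.stack([tr.positions for tr in trajs])
    vels = None
    if all(tr.velocities is not None for tr in trajs):
        vels = np.stack([tr.velocities for tr in trajs])
    dt = meta.get("dt")
    seed = meta.get("seed")
    return TrajectoryEnsemble(
        times=times,
        positions=positions,
        velocities=vels,
        dt=None if dt is None else float(dt),
        seed=None if seed is None else int(seed),
        params=ModelParams.from_dict(pdict) if pdict else None,
        scheme_tag=meta.get("scheme_tag", "unknown"),
    )


def read_spt_table(
    path: Union[str, os.PathLike],
    column_map: dict[str, Union[int, str]],
    delimiter: Optional[str] = None,
    skip_header: int = 0,
) -> Trajectory:
    """Read an external single-particle-tracking table.

    ``column_map`` maps the roles ``time``, ``x`` (and optionally ``y``,
    ``z``) to 0-based column indices or, when the file has a header row of
    names, to column names.  Times are shifted so the track starts at 0.
    """
    if "time" not in column_map or "x" not in column_map:
        raise ValueError("column_map needs at least 'time' and 'x'")
    by_name = any(isinstance(v, str) for v in column_map.values())
    if by_name:
        data = np.genfromtxt(path, names=True, delimiter=delimiter, skip_header=skip_header)
        get = lambda key: np.asarray(data[column_map[key]], dtype=float)
    else:
        raw = np.loadtxt(path, delimiter=delimiter, skiprows=skip_header, ndmin=2)
        get = lambda key: raw[:, int(column_map[key])]
    times = get("time")
    axes = [get(a) for a in ("x", "y", "z") if a in column_map]
    pos = axes[0] if len(axes) == 1 else np.column_stack(axes)
    return Trajectory(times=times - times[0], positions=pos, scheme_tag="external-spt")
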