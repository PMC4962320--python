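"""In-memory containers shared across the analytic, simulation and
estimation layers: statistic curves, regime reports and trajectory
ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .model import ModelParams

__all__ = [
    "StatCurve",
    "RegimeReport",
    "Trajectory",
    "TrajectoryEnsemble",
    "EBReport",
]

_CURVE_KINDS = {"msd", "tamsd", "vcf", "temperature"}
_MODEL_TAGS = {"udsbm", "sbm", "brownian", "empirical"}


@dataclass
class StatCurve:
    """A (time-or-lag, value) series for an MSD, TAMSD, VCF or temperature
    record, optionally with per-point standard errors.

    ``measurement_time`` is the total trace length t and is required for
    TAMSD curves, whose lag axis must satisfy max(lag) < t.
    """

    abscissa: np.ndarray
    values: np.ndarray
    stderr: Optional[np.ndarray] = None
    kind: str = "msd"
    model_tag: str = "empirical"
    measurement_time: Optional[float] = None
    params: Optional[ModelParams] = None

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.values.shape:
                raise ValueError("stderr shape must match values")
        if self.abscissa.shape != self.values.shape:
            raise ValueError("abscissa and values must have equal length")
        if self.kind not in _CURVE_KINDS:
            raise ValueError(f"kind must be one of {sorted(_CURVE_KINDS)}")
        if self.model_tag not in _MODEL_TAGS:
            raise ValueError(f"model_tag must be one of {sorted(_MODEL_TAGS)}")
        if self.abscissa.size:
            if np.any(self.abscissa < 0):
                raise ValueError("abscissa must be >= 0")
            if np.any(np.diff(self.abscissa) <= 0):
                raise ValueError("abscissa must be strictly increasing")
        if self.kind in ("msd", "tamsd") and np.any(self.values < -1e-300):
            raise ValueError(f"{self.kind} values must be >= 0")
        if self.kind == "tamsd":
            if self.measurement_time is None:
                raise ValueError("tamsd curves require measurement_time")
            if self.abscissa.size and self.abscissa[-1] >= self.measurement_time:
                raise ValueError("lags must be below the measurement time")

    def __len__(self) -> int:
        return self.abscissa.size


@dataclass
class RegimeReport:
    """Log-log slopes per time window plus predicted crossover times.

    ``windows`` are (lo, hi) abscissa intervals, ``slopes`` the fitted (or
    predicted) local log-log exponents and ``labels`` the regime each window
    is assigned to.  ``crossover_times`` are the model-predicted regime
    boundaries (1/gamma0, tau0 and, for time-averaged statistics, t/nu).
    """

    crossover_times: dict[str, float]
    windows: list[tuple[float, float]]
    slopes: list[float]
    labels: list[str]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.slopes)):
            raise ValueError("slopes must be finite")
        times = list(self.crossover_times.values())
        if any(b <= 0 for b in times):
            raise ValueError("crossover times must be positive")
        if sorted(times) != times:
            raise ValueError("crossover times must be sorted")
        if not (len(self.windows) == len(self.slopes) == len(self.labels)):
            raise ValueError("windows, slopes and labels must align")


_REGIME_LABELS = ("ballistic", "normal", "anomalous", "logarithmic", "intermediate")


def classify_slope(slope: float, alpha: Optional[float] = None) -> str:
    """Assign a regime label to a local log-log exponent."""
    if abs(slope - 2.0) < 0.1:
        return "ballistic"
    if abs(slope - 1.0) < 0.1:
        return "normal"
    if slope < 0.15:
        return "logarithmic"
    if alpha is not None and abs(slope - alpha) < 0.1:
        return "anomalous"
    if alpha is None and (slope < 0.9 or slope > 1.1):
        return "anomalous"
    return "intermediate"


@dataclass
class Trajectory:
    """A sampled trajectory: positions (and optionally velocities) on a
    time grid starting at t = 0.

    1D trajectories store positions of shape ``(n,)``; d-dimensional ones
    (e.g. granular-gas tracers) ``(n, d)``.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    dt: Optional[float] = None
    seed: Optional[int] = None
    params: Optional[ModelParams] = None
    scheme_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("trajectories start at t = 0")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def ndim_space(self) -> int:
        return 1 if self.positions.ndim == 1 else self.positions.shape[1]


@dataclass
class TrajectoryEnsemble:
    """N trajectories on a shared time grid, stored as dense arrays of
    shape (N, n_samples[, d])."""

    times: np.ndarray
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    dt: Optional[float] = None
    seed: Optional[int] = None
    params: Optional[ModelParams] = None
    scheme_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim < 2:
            raise ValueError("ensemble positions must be (N, n_samples[, d])")
        if self.positions.shape[1] != self.times.size:
            raise ValueError("positions second axis must match times")
        if self.positions.shape[0] < 1:
            raise ValueError("ensemble needs N >= 1 trajectories")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim_space(self) -> int:
        return 1 if self.positions.ndim == 2 else self.positions.shape[2]

    @property
    def measurement_time(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return self.n_traj

    def __getitem__(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            positions=self.positions[i],
            velocities=None if self.velocities is None else self.velocities[i],
            dt=self.dt,
            seed=self.seed,
            params=self.params,
            scheme_tag=self.scheme_tag,
        )

    def __iter__(self) -> Iterator[Trajectory]:
        return (self[i] for i in range(self.n_traj))


@dataclass
class EBReport:
    """Ergodicity-breaking and ageing diagnostics.

    ``ratio`` is the ensemble-averaged TAMSD divided by the ensemble MSD at
    matched (lag) times; unity within error signals ergodic behaviour.
    ``ageing_exponent`` is d log(TAMSD)/d log(t) at fixed lag; 0 for a
    stationary process, alpha - 1 for scaled Brownian motion.
    """

    lags: np.ndarray
    ratio: np.ndarray
    ratio_stderr: Optional[np.ndarray] = None
    ageing_exponent: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if np.any(self.ratio <= 0):
            raise ValueError("TAMSD/MSD ratio must be positive")
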