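"""Thermal protocol for (underdamped) scaled Brownian motion.

A particle of mass ``m`` moves in a bath whose temperature decays as a
power law,

    T(t) = T0 (1 + t/tau0)^(-2(1-alpha)),

with ``kB = 1``.  Local equilibrium of the bath fixes the damping rate to
scale as the thermal velocity, ``gamma(t) = gamma0 (1 + t/tau0)^(-(1-alpha))``,
and the time-local fluctuation-dissipation relation then gives the
diffusivity

    D(t) = T(t) / (m gamma(t)) = D0 (1 + t/tau0)^(alpha - 1).

``alpha = 1`` recovers ordinary Brownian motion with constant coefficients;
``alpha = 0`` is the ultraslow (logarithmic) limit realised by a granular
gas cooling under Haff's law, ``T ~ t^-2``.  The Langevin description is
controlled by the scale separation ``nu = tau0 * gamma0 >> 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "ValidityWarning",
    "temperature",
    "damping",
    "diffusivity",
    "damping_integral",
    "damping_integral_inverse",
]

#: below this value of nu = tau0*gamma0 the time-local fluctuation-dissipation
#: closure is marginal and asymptotic formulas degrade as O(1/nu)
NU_VALIDITY_THRESHOLD = 10.0


class ValidityWarning(UserWarning):
    """Raised when parameters leave the regime of validity (nu < 10)."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the cooling-bath protocol.

    Parameters
    ----------
    T0 : float
        Initial bath temperature (energy units, kB = 1).
    gamma0 : float
        Initial damping rate, 1/time.
    m : float
        Particle mass.
    tau0 : float
        Characteristic time of the temperature decay.
    alpha : float
        Anomalous diffusion exponent, >= 0.  ``alpha = 1`` is normal
        diffusion, ``0 < alpha < 1`` subdiffusion, ``alpha > 1``
        superdiffusion and ``alpha = 0`` ultraslow diffusion.

    Derived attributes ``D0 = T0/(gamma0 m)`` and ``nu = tau0*gamma0`` are
    never set directly.
    """

    T0: float = 1.0
    gamma0: float = 1.0
    m: float = 1.0
    tau0: float = 1.0
    alpha: float = 1.0
    nu_valid: bool = field(init=False, repr=False, default=True)

    def __post_init__(self) -> None:
        for name in ("T0", "gamma0", "m", "tau0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        object.__setattr__(self, "nu_valid", self.nu >= NU_VALIDITY_THRESHOLD)
        if not self.nu_valid and self.alpha != 1.0:
            warnings.warn(
                f"nu = tau0*gamma0 = {self.nu:g} < {NU_VALIDITY_THRESHOLD:g}: the "
                "time-local fluctuation-dissipation closure is marginal",
                ValidityWarning,
                stacklevel=2,
            )

    @property
    def D0(self) -> float:
        """Initial diffusivity T0/(gamma0*m)."""
        return self.T0 / (self.gamma0 * self.m)

    @property
    def nu(self) -> float:
        """Scale-separation parameter tau0*gamma0 (dimensionless)."""
        return self.tau0 * self.gamma0

    def to_dict(self) -> dict[str, float]:
        return {
            "T0": self.T0,
            "gamma0": self.gamma0,
            "m": self.m,
            "tau0": self.tau0,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        derived = {"D0", "nu"} & set(d)
        if derived:
            raise ValueError(
                f"{sorted(derived)} are derived quantities and cannot be set; "
                "provide T0, gamma0, m, tau0, alpha"
            )
        known = {"T0", "gamma0", "m", "tau0", "alpha"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def _maybe_scalar(x, scalar_in: bool):
    return float(x) if scalar_in else x


def temperature(params: ModelParams, t):
    """Bath temperature T(t) = T0 (1 + t/tau0)^(-2(1-alpha))."""
    scalar = np.isscalar(t)
    t = _check_time(t)
    out = params.T0 * np.exp(-2.0 * (1.0 - params.alpha) * np.log1p(t / params.tau0))
    return _maybe_scalar(out, scalar)


def damping(params: ModelParams, t):
    """Damping rate gamma(t) = gamma0 (1 + t/tau0)^(-(1-alpha))."""
    scalar = np.isscalar(t)
    t = _check_time(t)
    out = params.gamma0 * np.exp(-(1.0 - params.alpha) * np.log1p(t / params.tau0))
    return _maybe_scalar(out, scalar)


def diffusivity(params: ModelParams, t):
    """Diffusivity D(t) = D0 (1 + t/tau0)^(alpha-1) = T(t)/(m gamma(t))."""
    scalar = np.isscalar(t)
    t = _check_time(t)
    out = params.D0 * np.exp((params.alpha - 1.0) * np.log1p(t / params.tau0))
    return _maybe_scalar(out, scalar)


def damping_integral(params: ModelParams, t):
    """Integrated damping Gamma(t) = int_0^t gamma(s) ds.

    Closed forms: (nu/alpha) [(1 + t/tau0)^alpha - 1] for alpha > 0 and
    nu ln(1 + t/tau0) for alpha = 0 (evaluated exactly rather than as a
    numerical alpha -> 0 limit).
    """
    scalar = np.isscalar(t)
    t = _check_time(t)
    lt = np.log1p(t / params.tau0)
    if params.alpha == 0.0:
        out = params.nu * lt
    else:
        out = params.nu / params.alpha * np.expm1(params.alpha * lt)
    return _maybe_scalar(out, scalar)


def damping_integral_inverse(params: ModelParams, g):
    """Inverse of :func:`damping_integral`: the time t with Gamma(t) = g."""
    scalar = np.isscalar(g)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("Gamma must be >= 0")
    if params.alpha == 0.0:
        out = params.tau0 * np.expm1(g / params.nu)
    else:
        out = params.tau0 * np.expm1(np.log1p(params.alpha * g / params.nu) / params.alpha)
    return _maybe_scalar(out, scalar)
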