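"""Exact and asymptotic statistics of (underdamped) scaled Brownian motion.

The process is the linear Langevin equation

    m dv/dt = -m gamma(t) v + m gamma(t) sqrt(2 D(t)) xi(t),

with the power-law protocol of :mod:`udsbm.model`.  Everything here follows
from the two-point velocity correlation

    <v(t1) v(t2)> = e^{-(Gamma(t2) - Gamma(t1))}
                    [ <v0^2> e^{-2 Gamma(t1)}
                      + int_0^{Gamma(t1)} e^{-2w} (2 T(s_w)/m) dw ],

where Gamma is the integrated damping and s_w solves
Gamma(s_w) = Gamma(t1) - w.  Writing the correlation in the Gamma variable
keeps every exponential bounded by one, so the quadrature stays stable over
ten decades in time.

Ensemble moments are obtained from the equivalent closed moment equations

    d<v^2>/dt = -2 gamma (<v^2> - T/m),
    d<x v>/dt = <v^2> - gamma <x v>,
    d<x^2>/dt = 2 <x v>,

integrated in a relative parametrisation (deviations from the local
equilibrium values T/m and D) so that the slowly decaying moments never
lose precision.  The time-averaged MSD splits into the overdamped (scaled
Brownian motion) part, available in closed form, plus a negative inertial
correction Xi evaluated by nested quadrature.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate

from .containers import RegimeReport, StatCurve, classify_slope
from .model import (
    ModelParams,
    ValidityWarning,
    damping,
    damping_integral,
    diffusivity,
    temperature,
)

__all__ = [
    "vcf_exact",
    "vcf_asymptotic",
    "msd",
    "msd_curve",
    "sbm_msd",
    "tamsd_overdamped",
    "inertial_correction",
    "tamsd",
    "tamsd_curve",
    "asymptotic_regimes",
    "euler_constant_integral",
    "QuadratureError",
]

#: exponential weights e^{-w} below e^{-80} contribute nothing at float64
_W_CUT = 80.0


class QuadratureError(RuntimeError):
    """A quadrature did not converge to the requested accuracy."""


# ---------------------------------------------------------------------------
# scalar protocol closures in the integrated-damping variable


def _gamma_of_Gamma(params: ModelParams) -> Callable[[float], float]:
    """gamma(s) as a function of Gamma(s) (closed form, no inversion)."""
    g0, nu, a = params.gamma0, params.nu, params.alpha
    if a == 0.0:
        return lambda G: g0 * math.exp(-G / nu)
    p = (a - 1.0) / a
    return lambda G: g0 * (1.0 + a * G / nu) ** p


def _T_of_Gamma(params: ModelParams) -> Callable[[float], float]:
    """T(s) as a function of Gamma(s)."""
    T0, nu, a = params.T0, params.nu, params.alpha
    if a == 0.0:
        return lambda G: T0 * math.exp(-2.0 * G / nu)
    p = -2.0 * (1.0 - a) / a
    return lambda G: T0 * (1.0 + a * G / nu) ** p


# ---------------------------------------------------------------------------
# velocity correlation function


def vcf_exact(
    params: ModelParams,
    t1: float,
    t2: float,
    v0_variance: Optional[float] = None,
    rtol: float = 1e-10,
) -> float:
    """Exact two-point velocity correlation <v(t1) v(t2)>.

    ``v0_variance`` is the variance of the initial velocity; the default is
    the thermal value T0/m, a cold start uses 0.  Arguments are symmetrised
    so the order of t1, t2 does not matter.
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("times must be >= 0")
    if t1 > t2:
        t1, t2 = t2, t1
    if v0_variance is None:
        v0_variance = params.T0 / params.m
    G1 = damping_integral(params, t1)
    G2 = damping_integral(params, t2)
    T_of_G = _T_of_Gamma(params)
    m = params.m

    W = min(G1, _W_CUT / 2.0)
    if W > 0.0:
        val, err = integrate.quad(
            lambda w: 2.0 * T_of_G(G1 - w) / m * math.exp(-2.0 * w),
            0.0,
            W,
            epsabs=0.0,
            epsrel=rtol,
            limit=200,
        )
        scale = abs(val) + v0_variance * math.exp(-2.0 * min(G1, _W_CUT))
        if err > 1e-6 * scale:
            raise QuadratureError(
                f"velocity-correlation quadrature did not converge: "
                f"t1={t1:g}, t2={t2:g}, estimated error {err:g} vs value {val:g}"
            )
    else:
        val = 0.0
    equal_time = v0_variance * math.exp(-2.0 * min(G1, _W_CUT)) + val
    dG = G2 - G1
    return equal_time * (math.exp(-dG) if dG < _W_CUT * 10 else 0.0)


def vcf_asymptotic(params: ModelParams, t1: float, t2: float) -> float:
    """Local-equilibrium velocity correlation (T(t1)/m) e^{-(Gamma2-Gamma1)}.

    Valid for t1 >> 1/gamma(t1) and nu >> 1; agrees with :func:`vcf_exact`
    to O(1/nu).  For alpha = 1 this is the exponential correlation of the
    constant-coefficient Langevin equation.
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("times must be >= 0")
    if t1 > t2:
        t1, t2 = t2, t1
    if not params.nu_valid:
        warnings.warn(
            f"nu = {params.nu:g} < 10: asymptotic velocity correlation is marginal",
            ValidityWarning,
            stacklevel=2,
        )
    dG = damping_integral(params, t2) - damping_integral(params, t1)
    decay = math.exp(-dG) if dG < _W_CUT * 10 else 0.0
    return temperature(params, t1) / params.m * decay


# ---------------------------------------------------------------------------
# moment equations (ensemble MSD and the helpers for the inertial TAMSD term)


def _moment_solution(
    params: ModelParams,
    times: np.ndarray,
    v0_variance: Optional[float] = None,
):
    """Solve the second-moment equations on ``times`` (sorted, >= 0).

    Returns (E2, xv, deficit) where E2 = <v^2>, xv = <x v> and
    deficit = <x^2> - S(t) with S the overdamped (scaled Brownian motion)
    MSD.  The integration uses the relative variables
    e = E2 m/T - 1 and f = xv/D - 1, which stay O(1/nu) at long times and
    avoid the catastrophic loss of precision of the raw moments.
    """
    if v0_variance is None:
        v0_variance = params.T0 / params.m
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.array([]), np.array([]), np.array([])
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    t_max = float(times[-1])
    tau0, a = params.tau0, params.alpha

    def rhs(t, y):
        e, f, _ = y
        g = damping(params, t)
        D = diffusivity(params, t)
        c = (1.0 - a) / (tau0 + t)
        return (
            -2.0 * g * e + 2.0 * c * (1.0 + e),
            g * (e - f) + c * (1.0 + f),
            2.0 * D * f,
        )

    def jac(t, y):
        g = damping(params, t)
        D = diffusivity(params, t)
        c = (1.0 - a) / (tau0 + t)
        return [
            [-2.0 * g + 2.0 * c, 0.0, 0.0],
            [g, -g + c, 0.0],
            [0.0, 2.0 * D, 0.0],
        ]

    y0 = (v0_variance * params.m / params.T0 - 1.0, -1.0, 0.0)
    if t_max == 0.0:
        sol_y = np.array([y0]).T.repeat(times.size, axis=1)
    else:
        t_eval = times if times[0] >= 0 else times
        sol = integrate.solve_ivp(
            rhs,
            (0.0, t_max),
            y0,
            method="LSODA",
            jac=jac,
            t_eval=t_eval,
            rtol=1e-11,
            atol=(1e-13, 1e-13, 1e-13 * params.D0 / params.gamma0),
        )
        if not sol.success:
            raise QuadratureError(f"moment-equation integration failed: {sol.message}")
        sol_y = sol.y
    e, f, R = sol_y
    E2 = temperature(params, times) / params.m * (1.0 + e)
    xv = diffusivity(params, times) * (1.0 + f)
    return E2, xv, R


# ---------------------------------------------------------------------------
# mean squared displacement


def sbm_msd(params: ModelParams, t):
    """Closed-form overdamped (scaled Brownian motion) MSD 2 int_0^t D(s) ds.

    Equals (2 D0 tau0/alpha) [(1 + t/tau0)^alpha - 1] for alpha > 0 and
    2 D0 tau0 ln(1 + t/tau0) for alpha = 0.
    """
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    lt = np.log1p(t / params.tau0)
    if params.alpha == 0.0:
        out = 2.0 * params.D0 * params.tau0 * lt
    else:
        out = 2.0 * params.D0 * params.tau0 / params.alpha * np.expm1(params.alpha * lt)
    return float(out) if scalar else out


def _sbm_msd_antiderivative(params: ModelParams, t):
    """P(t) = int_0^t S(u) du for the closed-form overdamped MSD S."""
    t = np.asarray(t, dtype=float)
    tau0, a, D0 = params.tau0, params.alpha, params.D0
    lt = np.log1p(t / tau0)
    if a == 0.0:
        return 2.0 * D0 * tau0 * ((tau0 + t) * lt - t)
    return 2.0 * D0 * tau0 / a * (tau0 / (a + 1.0) * np.expm1((a + 1.0) * lt) - t)


def msd(
    params: ModelParams,
    t,
    model: str = "udsbm",
    v0_variance: Optional[float] = None,
):
    """Ensemble MSD <x^2(t)>.

    ``model="sbm"`` returns the closed-form overdamped result;
    ``model="udsbm"`` integrates the exact second-moment equations of the
    underdamped process (ballistic -> normal -> anomalous/logarithmic
    cascade).  The default initial velocity is thermal, variance T0/m.
    """
    if model not in ("udsbm", "sbm"):
        raise ValueError("model must be 'udsbm' or 'sbm'")
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if model == "sbm":
        out = sbm_msd(params, t_arr)
    else:
        order = np.argsort(t_arr)
        sorted_t = t_arr[order]
        _, _, deficit = _moment_solution(params, sorted_t, v0_variance)
        out = np.empty_like(t_arr)
        out[order] = sbm_msd(params, sorted_t) + deficit
    return float(out[0]) if scalar else out


def msd_curve(
    params: ModelParams,
    times: Sequence[float],
    model: str = "udsbm",
    v0_variance: Optional[float] = None,
) -> StatCurve:
    """MSD on a time grid, packaged as a :class:`StatCurve`."""
    times = np.asarray(times, dtype=float)
    return StatCurve(
        abscissa=times,
        values=msd(params, times, model=model, v0_variance=v0_variance),
        kind="msd",
        model_tag=model,
        params=params,
    )


# ---------------------------------------------------------------------------
# time-averaged MSD


def _sbm_increment(params: ModelParams, tprime, lag):
    """S(t'+lag) - S(t') evaluated without cancellation (expm1/log1p)."""
    tprime = np.asarray(tprime, dtype=float)
    tau0, a, D0 = params.tau0, params.alpha, params.D0
    dlt = np.log1p(lag / (tau0 + tprime))
    if a == 0.0:
        return 2.0 * D0 * tau0 * dlt
    lt = np.log1p(tprime / tau0)
    return 2.0 * D0 * tau0 / a * np.exp(a * lt) * np.expm1(a * dlt)


def tamsd_overdamped(params: ModelParams, lag, t: float, max_lag_fraction: float = 0.99):
    """Overdamped (scaled Brownian motion) time-averaged MSD.

    delta0(lag; t) = (t - lag)^{-1} int_0^{t-lag} [S(t'+lag) - S(t')] dt'
    with S the closed-form overdamped MSD.  Although the double integral
    also has a closed form in terms of the antiderivative of S, that
    expression cancels catastrophically for lag << t, so the outer average
    is taken by composite Gauss-Legendre quadrature of the stable increment
    S(t'+lag) - S(t'); the integrand is a smooth power law and the panels
    resolve every relevant scale, so the result is accurate to close to
    machine precision.  The estimator has a pole at lag -> t: lags beyond
    ``max_lag_fraction * t`` are refused.
    """
    scalar = np.isscalar(lag)
    lag = np.atleast_1d(np.asarray(lag, dtype=float))
    if np.any(lag <= 0):
        raise ValueError("lag must be > 0")
    if np.any(lag >= max_lag_fraction * t):
        raise ValueError(
            f"lag must be < {max_lag_fraction:g} * t (the time average has a pole "
            "at lag = t); pass max_lag_fraction to override"
        )
    x, w = _gl(10)
    out = np.empty_like(lag)
    for k, L in enumerate(lag):
        bounds = _outer_panels(t - L, params.tau0 / 8.0, 64)
        lo, hi = bounds[:-1], bounds[1:]
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        nodes = mid[:, None] + half[:, None] * x
        vals = _sbm_increment(params, nodes, L)
        out[k] = float(np.sum(half[:, None] * w * vals)) / (t - L)
    return float(out[0]) if scalar else out


def _h_factory(params: ModelParams, rtol: float = 1e-12):
    """Return h(G1, dG) = int_{t1}^{t2} e^{-(Gamma(s)-Gamma(t1))} ds as a
    function of Gamma(t1) and Gamma(t2)-Gamma(t1), plus an error tally."""
    gamma_of_G = _gamma_of_Gamma(params)
    errors: list[float] = []

    def h(G1: float, dG: float) -> float:
        if dG <= 0.0:
            return 0.0
        W = min(dG, _W_CUT)
        val, err = integrate.quad(
            lambda w: math.exp(-w) / gamma_of_G(G1 + w),
            0.0,
            W,
            epsabs=0.0,
            epsrel=rtol,
            limit=200,
        )
        errors.append(err)
        return val

    return h, errors


def _outer_panels(t_upper: float, small: float, n_panels: int):
    """Panel boundaries on [0, t_upper]: one linear panel near zero, then a
    geometric progression; resolves the 1/gamma0- and tau0-scale structure
    of the windowed increments while reaching out to t."""
    a = min(small, t_upper / 4.0)
    bounds = np.concatenate(([0.0], np.geomspace(a, t_upper, n_panels)))
    return bounds


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def inertial_correction(
    params: ModelParams,
    lag,
    t: float,
    v0_variance: Optional[float] = None,
    n_panels: int = 48,
    n_gauss: int = 7,
    max_lag_fraction: float = 0.99,
    check_error: bool = True,
):
    """Inertial correction Xi(lag; t) to the time-averaged MSD.

    Defined operationally as the full underdamped time-averaged MSD minus
    the overdamped closed form, computed without cancellation from the
    exact windowed increment variance

        g(t', lag) = S(t'+lag) - S(t') + d(t'),
        d(t')      = R(t'+lag) - R(t') - 2 <x v>(t') h(t', t'+lag),

    where R is the MSD deficit and h integrates the velocity relaxation
    over the window.  Xi is the t'-average of d, taken with composite
    Gauss-Legendre quadrature on a near-geometric panel grid.  Xi <= 0:
    inertia can only reduce the time-averaged MSD.
    """
    scalar = np.isscalar(lag)
    lags = np.atleast_1d(np.asarray(lag, dtype=float))
    if np.any(lags <= 0):
        raise ValueError("lag must be > 0")
    if np.any(lags >= max_lag_fraction * t):
        raise ValueError(f"lag must be < {max_lag_fraction:g} * t")

    small = min(1.0 / params.gamma0, params.tau0) / 8.0
    panel_sets = [_outer_panels(t - L, small, n_panels) for L in lags]

    # one moment-equation solve over the union of all needed node times
    x_f, w_f = _gl(n_gauss)
    x_c, w_c = _gl(max(2, n_gauss - 3))
    node_list = []
    for bounds, L in zip(panel_sets, lags):
        lo, hi = bounds[:-1], bounds[1:]
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        nodes = np.concatenate(
            [(mid[:, None] + half[:, None] * x_f).ravel(),
             (mid[:, None] + half[:, None] * x_c).ravel()]
        )
        node_list.append(np.concatenate([nodes, nodes + L]))
    all_times = np.unique(np.concatenate(node_list))
    E2, xv, R = _moment_solution(params, all_times, v0_variance)
    xv_at = dict(zip(all_times.tolist(), xv.tolist()))
    R_at = dict(zip(all_times.tolist(), R.tolist()))
    G_at = dict(zip(all_times.tolist(), np.atleast_1d(damping_integral(params, all_times)).tolist()))

    h_func, h_errors = _h_factory(params)

    def integrand(tp: float, L: float) -> float:
        t2 = tp + L
        G1 = G_at[tp]
        return R_at[t2] - R_at[tp] - 2.0 * xv_at[tp] * h_func(G1, G_at[t2] - G1)

    out = np.empty_like(lags)
    err_est = np.empty_like(lags)
    for k, (bounds, L) in enumerate(zip(panel_sets, lags)):
        lo, hi = bounds[:-1], bounds[1:]
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        fine = coarse = 0.0
        for mu, hh in zip(mid, half):
            vals_f = [integrand(mu + hh * x, L) for x in x_f]
            vals_c = [integrand(mu + hh * x, L) for x in x_c]
            fine += hh * float(np.dot(w_f, vals_f))
            coarse += hh * float(np.dot(w_c, vals_c))
        out[k] = fine / (t - L)
        err_est[k] = abs(fine - coarse) / (t - L)

    if check_error:
        total = tamsd_overdamped(params, lags, t, max_lag_fraction) + out
        bad = err_est > 0.01 * np.abs(total) + 1e-300
        if np.any(bad):
            i = int(np.argmax(err_est / (np.abs(total) + 1e-300)))
            raise QuadratureError(
                "inertial-correction quadrature error exceeds 1% of the "
                f"time-averaged MSD at lag={lags[i]:g}: estimated error "
                f"{err_est[i]:g} vs value {total[i]:g}; increase n_panels/n_gauss"
            )
    return float(out[0]) if scalar else out


def tamsd(
    params: ModelParams,
    lag,
    t: float,
    model: str = "udsbm",
    v0_variance: Optional[float] = None,
    **quad_opts,
):
    """Analytic (ensemble-averaged) time-averaged MSD at measurement time t.

    ``model="sbm"`` is the overdamped closed form alone; ``model="udsbm"``
    adds the (negative) inertial correction Xi.  For alpha = 1 the result
    equals the ensemble MSD at the same lag (ergodicity); for alpha < 1 it
    depends explicitly on t (ageing).
    """
    if model not in ("udsbm", "sbm"):
        raise ValueError("model must be 'udsbm' or 'sbm'")
    base = tamsd_overdamped(
        params, lag, t, quad_opts.get("max_lag_fraction", 0.99)
    )
    if model == "sbm":
        return base
    return base + inertial_correction(params, lag, t, v0_variance, **quad_opts)


def tamsd_curve(
    params: ModelParams,
    lags: Sequence[float],
    t: float,
    model: str = "udsbm",
    v0_variance: Optional[float] = None,
    **quad_opts,
) -> StatCurve:
    """Time-averaged MSD on a lag grid, packaged as a :class:`StatCurve`."""
    lags = np.asarray(lags, dtype=float)
    return StatCurve(
        abscissa=lags,
        values=tamsd(params, lags, t, model=model, v0_variance=v0_variance, **quad_opts),
        kind="tamsd",
        model_tag=model,
        measurement_time=t,
        params=params,
    )


# ---------------------------------------------------------------------------
# regime structure


def _long_time_exponent(params: ModelParams) -> tuple[float, str]:
    if params.alpha == 0.0:
        return 0.0, "logarithmic"
    if params.alpha == 1.0:
        return 1.0, "normal"
    return params.alpha, "anomalous"


def asymptotic_regimes(
    params: ModelParams,
    t_range: tuple[float, float],
    statistic: str = "msd",
    measurement_time: Optional[float] = None,
    points_per_window: int = 8,
) -> RegimeReport:
    """Predicted crossover times and fitted log-log slopes per regime.

    For the MSD the boundaries are 1/gamma0 (ballistic -> normal) and tau0
    (normal -> anomalous/logarithmic).  For the time-averaged MSD of a
    subdiffusive or ultraslow process the additional boundary t/nu marks
    where the inertial correction stops competing with the overdamped term.
    Slopes are fitted to the analytic curve inside each window (windows are
    shrunk away from the crossovers before fitting).
    """
    if statistic not in ("msd", "tamsd"):
        raise ValueError("statistic must be 'msd' or 'tamsd'")
    lo, hi = float(t_range[0]), float(t_range[1])
    if not (0 < lo < hi):
        raise ValueError("range must be positive and increasing")

    boundaries = {"1/gamma0": 1.0 / params.gamma0}
    long_exp, long_label = _long_time_exponent(params)
    if params.alpha != 1.0:
        boundaries["tau0"] = params.tau0
    if statistic == "tamsd":
        if measurement_time is None:
            raise ValueError("tamsd regimes require measurement_time")
        if params.alpha < 1.0:
            boundaries["t/nu"] = measurement_time / params.nu
    boundaries = dict(sorted(boundaries.items(), key=lambda kv: kv[1]))

    edges = [lo] + [b for b in boundaries.values() if lo < b < hi] + [hi]
    expected = [2.0]  # ballistic below 1/gamma0
    labels_pred = ["ballistic"]
    names = list(boundaries)
    for name in names:
        if name == "1/gamma0":
            expected.append(1.0)
            labels_pred.append("normal")
        elif name == "tau0":
            if statistic == "msd" or params.alpha >= 1.0:
                expected.append(long_exp)
                labels_pred.append(long_label)
            else:
                expected.append(1.0)
                labels_pred.append("intermediate")
        elif name == "t/nu":
            expected.append(long_exp)
            labels_pred.append(long_label)

    windows, slopes, labels = [], [], []
    for i in range(len(edges) - 1):
        wlo, whi = edges[i], edges[i + 1]
        if whi / wlo < 1.5:
            continue
        # fit away from the contaminated side(s): crossover transients sit
        # at the top of the first window, the bottom of the last, both for
        # interior windows
        span = whi / wlo
        if i == 0:
            f_lo, f_hi = 0.05, 0.5
        elif i == len(edges) - 2:
            f_lo, f_hi = 0.5, 0.95
        else:
            f_lo, f_hi = 0.35, 0.65
        grid = np.geomspace(wlo * span**f_lo, wlo * span**f_hi, points_per_window)
        if statistic == "msd":
            vals = msd(params, grid, model="udsbm")
        else:
            vals = tamsd(params, grid, measurement_time, model="udsbm")
        good = vals > 0
        if good.sum() < 3:
            continue
        slope = float(np.polyfit(np.log(grid[good]), np.log(vals[good]), 1)[0])
        windows.append((wlo, whi))
        slopes.append(slope)
        labels.append(classify_slope(slope, params.alpha))
    return RegimeReport(
        crossover_times=boundaries, windows=windows, slopes=slopes, labels=labels
    )


# ---------------------------------------------------------------------------
# special constants


def euler_constant_integral(rtol: float = 1e-12) -> float:
    """Euler's constant as the quadrature -int_0^inf e^{-y} ln y dy.

    This constant (0.5772...) enters the long-lag expansion of the
    ultraslow time-averaged MSD through the digamma function, -psi(1).
    """
    f = lambda y: -math.exp(-y) * math.log(y)
    v1, e1 = integrate.quad(f, 0.0, 1.0, epsabs=0.0, epsrel=rtol, limit=200)
    v2, e2 = integrate.quad(f, 1.0, 60.0, epsabs=1e-16, epsrel=rtol, limit=200)
    if e1 + e2 > max(10.0 * rtol, 1e-8):
        raise QuadratureError("Euler-constant quadrature did not converge")
    return v1 + v2
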