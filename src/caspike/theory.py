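"""Mean-adaptation theory of the store-depleted integrate-and-fire model.

With the store frozen at a level cer, the ci dynamics reduce to a
one-dimensional diffusion whose stationary firing rate follows from the
classic first-passage quadrature

    r0(cer)^-1 = int_cR^cT dc1 e^{-h(c1)} int_{-inf}^{c1} dc2 e^{h(c2)} / D(c2),
    h(c)      = int_cR^c dc' [f(c') + D'(c')] / D(c'),

with the reset cR = ci0*cer and all coefficients frozen at cer.  A
second, independent relation follows from the stationary balance of
store depletion and replenishment,

    r0 = (1 - cer) / (eps_hat * tau_er * cer),   eps_hat = eps/(1 - eps/2),

where eps_hat corrects for the biased sampling of cer at spike times.
The first relation increases with cer, the second decreases, so their
intersection fixes the self-consistent stationary state (r0*, cer*).

The interval variance is evaluated through the first-passage moment
hierarchy (T2 - T1^2); the transient of the ensemble mean store level is
approximated by linearizing the rate around cer*, which yields a
Riccati equation for <cer(t)> with relaxation timescale tau_theo.

Numerics: all quadratures run on a dense ci grid in log space
(``np.logaddexp.accumulate``) because e^{+-h} spans thousands of orders
of magnitude near the reflecting region where D -> 0.  The lower
integration limit is the point where the opening rate vanishes (ci = 0);
contributions below any level where the inner integrand falls under
1e-15 of its maximum are automatically negligible in this scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .cluster import ClusterStats, cluster_stats
from .params import ModelParams
from .simulate import LangevinCoefficients, langevin_coefficients

__all__ = [
    "TheoryResult",
    "TransientPrediction",
    "h_function",
    "firing_rate_fixed_cer",
    "balance_rate",
    "self_consistent_state",
    "isi_variance_fixed_cer",
    "theoretical_timescale",
    "mean_cer_trajectory",
    "transient_predictions",
]

_TINY = 1e-300


@dataclass(frozen=True)
class TheoryResult:
    r0_star: float
    cer_star: float
    conditional_mean_pre_spike: float
    eps_hat: float
    isi_mean: float
    isi_var: float
    cv: float
    tau_theo: float | None = None
    r0_derivative: float | None = None


@dataclass(frozen=True)
class TransientPrediction:
    T0_pred: float
    T_inf_pred: float
    delta_T: float
    n_tr_pred: float


def eps_hat(eps: float) -> float:
    """Biased-sampling corrected depletion amplitude eps/(1 - eps/2)."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    return eps / (1.0 - eps / 2.0)


def h_function(coeffs: LangevinCoefficients, cer_value: float, c) -> float:
    """h(c) = int_{cR}^{c} [f + D'] / D at frozen cer (adaptive quadrature)."""
    cR = coeffs.params.ci0 * cer_value

    def integrand(x):
        D = coeffs.D(x, cer_value)
        if D <= 0:
            raise ZeroDivisionError(f"D vanishes at ci={x}: h undefined on the path")
        return (coeffs.f(x, cer_value) + coeffs.D_prime(x, cer_value)) / D

    if np.ndim(c) == 0:
        val, _ = quad(integrand, cR, float(c), limit=200)
        return val
    return np.array([h_function(coeffs, cer_value, ci) for ci in c])


def _frozen_grid(coeffs: LangevinCoefficients, cer_value: float, n_grid: int):
    """Dense ci grid on (0, cT] with frozen-cer drift and diffusion."""
    p = coeffs.params
    cT = p.c_threshold
    c = np.linspace(cT / n_grid, cT, n_grid)
    f = coeffs.f(c, cer_value)
    D = np.maximum(coeffs.D(c, cer_value), _TINY)
    Dp = coeffs.D_prime(c, cer_value)
    return c, f, D, Dp


def _fpt_mean_var(c, f, D, Dp, cR):
    """Mean and variance of the first-passage time cR -> c[-1].

    Log-space trapezoid evaluation of the moment-hierarchy quadratures;
    reflecting natural boundary at the lower end, absorbing at c[-1].
    """
    phi = (f + Dp) / D
    dc = np.diff(c)
    h = np.concatenate([[0.0], np.cumsum(0.5 * (phi[1:] + phi[:-1]) * dc)])
    h -= h.max()
    lg = h - np.log(D)
    lgmid = 0.5 * (lg[1:] + lg[:-1]) + np.log(dc)
    linner = np.concatenate([[-np.inf], np.logaddexp.accumulate(lgmid)])
    # local mean-passage density r(c) = e^{-h} int e^{h}/D; finite on the
    # physically visited range -- exponents are clipped because trapezoid
    # error in the singular region far below reset can produce spurious
    # huge values there (they carry zero weight downstream)
    r = np.exp(np.clip(linner - h, -745.0, 700.0))

    def _tail_integral(y):
        # int_{c}^{cT} y dc, accumulated from the right to avoid
        # cancellation against the (irrelevant) deep-subthreshold part
        seg = 0.5 * (y[1:] + y[:-1]) * dc
        return np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])

    T1loc = _tail_integral(r)  # mean passage time started from level c
    T1 = float(np.interp(cR, c, T1loc))
    with np.errstate(divide="ignore"):
        lgT = lg + np.log(np.maximum(T1loc, _TINY))
    lgTmid = 0.5 * (lgT[1:] + lgT[:-1]) + np.log(dc)
    lJ = np.concatenate([[-np.inf], np.logaddexp.accumulate(lgTmid)])
    g2 = np.exp(np.clip(lJ - h, -745.0, 700.0))
    T2 = 2.0 * float(np.interp(cR, c, _tail_integral(g2)))
    return T1, max(T2 - T1 * T1, 0.0)


def _coeffs(params, stats) -> LangevinCoefficients:
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    return langevin_coefficients(params, stats)


def firing_rate_fixed_cer(
    params: ModelParams,
    stats: ClusterStats | None = None,
    cer_value: float = 1.0,
    n_grid: int = 4000,
) -> float:
    """Stationary firing rate with the store frozen at cer_value, 1/s."""
    if not 0.0 < cer_value <= 1.0:
        raise ValueError("cer_value must lie in (0, 1]")
    co = _coeffs(params, stats)
    if params.p == 0:
        return 0.0
    c, f, D, Dp = _frozen_grid(co, cer_value, n_grid)
    T1, _ = _fpt_mean_var(c, f, D, Dp, params.ci0 * cer_value)
    if not np.isfinite(T1) or T1 <= 0:
        return 0.0
    return 1.0 / T1


def isi_variance_fixed_cer(
    params: ModelParams,
    stats: ClusterStats | None = None,
    cer_value: float = 1.0,
    n_grid: int = 4000,
):
    """Frozen-store interval variance <dT^2> and CV from the moment hierarchy."""
    if not 0.0 < cer_value <= 1.0:
        raise ValueError("cer_value must lie in (0, 1]")
    co = _coeffs(params, stats)
    c, f, D, Dp = _frozen_grid(co, cer_value, n_grid)
    T1, var = _fpt_mean_var(c, f, D, Dp, params.ci0 * cer_value)
    if not np.isfinite(T1) or T1 <= 0:
        raise FloatingPointError("non-spiking configuration: variance undefined")
    return var, float(np.sqrt(var) / T1)


def balance_rate(cer_value: float, tau_er: float, eps: float) -> float:
    """Firing rate required for depletion/replenishment balance at cer_value."""
    if not 0.0 < cer_value <= 1.0:
        raise ValueError("cer_value must lie in (0, 1]")
    return (1.0 - cer_value) / (eps_hat(eps) * tau_er * cer_value)


def self_consistent_state(
    params: ModelParams,
    stats: ClusterStats | None = None,
    n_grid: int = 4000,
    with_timescale: bool = True,
) -> TheoryResult:
    """Intersect the first-passage rate with the store-balance rate.

    The first is increasing, the second decreasing in cer, so the
    intersection on (0, 1] is unique; it is bracketed and refined until
    the residual |r_quad - r_balance| < 1e-8 * max(r, 1e-6).
    """
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    eh = eps_hat(params.eps)

    def rq(x):
        return firing_rate_fixed_cer(params, stats, x, n_grid)

    if params.eps == 0.0 or params.tau_er <= 0:
        cer_star, r0 = 1.0, rq(1.0)
    else:
        def gap(x):
            return rq(x) - balance_rate(x, params.tau_er, params.eps)

        lo, hi = 1e-3, 1.0 - 1e-12
        if rq(1.0) <= 0.0:
            # degenerate: the model cannot spike even at a full store
            var, cv = np.nan, np.nan
            return TheoryResult(0.0, 1.0, 1.0 / (1 - params.eps / 2), eh,
                                np.inf, np.nan, np.nan)
        if gap(lo) >= 0:  # even a nearly empty store sustains the balance
            cer_star = brentq(gap, lo, hi, xtol=1e-12) if gap(hi) < 0 else lo
        else:
            cer_star = brentq(gap, lo, hi, xtol=1e-12)
        r0 = rq(cer_star)
        rb = balance_rate(cer_star, params.tau_er, params.eps)
        if abs(r0 - rb) > 1e-8 * max(r0, 1e-6):
            # one Newton-polish pass on a finer grid
            cer_star = brentq(
                lambda x: firing_rate_fixed_cer(params, stats, x, 2 * n_grid)
                - balance_rate(x, params.tau_er, params.eps),
                max(lo, cer_star - 1e-3), min(hi, cer_star + 1e-3), xtol=1e-14,
            )
            r0 = firing_rate_fixed_cer(params, stats, cer_star, 2 * n_grid)
    var, cv = isi_variance_fixed_cer(params, stats, cer_star, n_grid)
    isi_mean = 1.0 / r0 if r0 > 0 else np.inf
    res = TheoryResult(
        r0_star=r0,
        cer_star=cer_star,
        conditional_mean_pre_spike=cer_star / (1.0 - params.eps / 2.0),
        eps_hat=eh,
        isi_mean=isi_mean,
        isi_var=var,
        cv=cv,
    )
    if with_timescale and r0 > 0:
        tau_theo, r0p = theoretical_timescale(params, stats, res, n_grid=n_grid)
        res = TheoryResult(**{**res.__dict__, "tau_theo": tau_theo, "r0_derivative": r0p})
    return res


def rate_derivative(
    params: ModelParams,
    stats: ClusterStats,
    cer_value: float,
    rel_step: float = 1e-3,
    n_grid: int = 4000,
) -> float:
    """Central-difference derivative r0'(cer) of the frozen-store rate."""
    hstep = rel_step * cer_value
    hi = min(cer_value + hstep, 1.0)
    lo = cer_value - hstep
    rhi = firing_rate_fixed_cer(params, stats, hi, n_grid)
    rlo = firing_rate_fixed_cer(params, stats, lo, n_grid)
    return (rhi - rlo) / (hi - lo)


def theoretical_timescale(
    params: ModelParams,
    stats: ClusterStats | None = None,
    result: TheoryResult | None = None,
    n_grid: int = 4000,
):
    """Relaxation timescale tau_theo of the linearized <cer(t)> dynamics.

    tau_theo = tau_er / sqrt((1 + eh*tau_er*(r0* - r0'*x*))^2 + 4*eh*tau_er*r0'),
    the inverse square-rooted discriminant of the Riccati equation for
    the ensemble-mean store level; equal to tau_er when eps = 0.
    """
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    if result is None:
        result = self_consistent_state(params, stats, n_grid, with_timescale=False)
    if params.eps == 0.0:
        return params.tau_er, 0.0
    x = result.cer_star
    r0 = result.r0_star
    r0p = rate_derivative(params, stats, x, n_grid=n_grid)
    eh = eps_hat(params.eps)
    radicand = (1.0 + eh * params.tau_er * (r0 - r0p * x)) ** 2 + 4.0 * eh * params.tau_er * r0p
    if radicand <= 0:
        raise FloatingPointError("negative radicand: linearization invalid here")
    return params.tau_er / np.sqrt(radicand), r0p


def mean_cer_trajectory(result: TheoryResult, tau_theo: float, t, x0: float = 1.0):
    """Predicted ensemble-mean store level <cer(t)> after stimulus onset.

    Returns (moebius, single_exp): the Riccati-derived Moebius form and
    its first-order-in-(x0 - x*) single-exponential reduction.  Both
    satisfy x(0) = x0 and x(inf) = x*.
    """
    t = np.asarray(t, dtype=float)
    xs = result.cer_star
    e = np.exp(-t / tau_theo)
    moebius = xs * ((x0 + xs) + (x0 - xs) * e) / ((x0 + xs) - (x0 - xs) * e)
    single = xs + (x0 - xs) * e
    return moebius, single


def integrate_mean_cer_ode(
    params: ModelParams,
    stats: ClusterStats,
    t_grid,
    x0: float = 1.0,
    n_grid: int = 2000,
):
    """Numerically integrate the nonlinear mean-field store equation
    d<cer>/dt = -(x-1)/tau_er - eps_hat * x * r0(x)  (oracle for the
    Moebius approximation)."""
    eh = eps_hat(params.eps)
    xg = np.linspace(0.2, 1.0, 33)
    rg = np.array([firing_rate_fixed_cer(params, stats, x, n_grid) for x in xg])

    def rhs(t, y):
        r = np.interp(y[0], xg, rg)
        return [-(y[0] - 1.0) / params.tau_er - eh * y[0] * r]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [x0], t_eval=t_grid,
                    rtol=1e-8, atol=1e-10, method="LSODA")
    return sol.y[0]


def transient_predictions(
    params: ModelParams,
    stats: ClusterStats | None = None,
    n_grid: int = 4000,
) -> TransientPrediction:
    """Predicted first/stationary intervals and transient length.

    T0 = 1/r0(cer=1) (independent of tau_er and eps), T_inf = 1/r0(cer*),
    n_tr = tau_theo / T0 (an upper bound on the fitted count).
    """
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    r1 = firing_rate_fixed_cer(params, stats, 1.0, n_grid)
    if r1 <= 0:
        raise ValueError("r0(cer=1) = 0: model does not spike from a full store")
    res = self_consistent_state(params, stats, n_grid)
    T0 = 1.0 / r1
    T_inf = 1.0 / res.r0_star if res.r0_star > 0 else np.inf
    tau_theo = res.tau_theo if res.tau_theo is not None else params.tau_er
    return TransientPrediction(
        T0_pred=T0, T_inf_pred=T_inf, delta_T=T_inf - T0, n_tr_pred=tau_theo / T0
    )
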