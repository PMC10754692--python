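"""Stochastic simulation of the two-component model.

Two routes are provided:

* ``simulate_two_component`` -- the hybrid scheme: exact (Gillespie)
  jumps of the K cluster chains with propensities frozen over each
  integration step, coupled to a fixed-step Euler update of ci using the
  time-average of the open-channel count over the step, and exact
  exponential relaxation of cer.

* ``simulate_langevin`` -- the diffusion approximation: the puff current
  is replaced by Gaussian white noise with mean p*cer*K*mu_x(ci) and
  intensity (p*cer)^2*K*D_x(ci).  The integrator is Heun
  (predictor-corrector) plus a D'/2 drift term so that its Fokker-Planck
  drift is f + D', matching the kinetic-form operator used by the
  stationary rate theory; without that term a Heun scheme realizes
  f + D'/2 and its first-passage statistics disagree measurably with the
  quadrature in the excitable regime.

Both apply the same fire-and-reset rule: when ci crosses cT (located by
linear interpolation within the step) a spike time is recorded,
cer <- (1-eps)*cer, then ci <- ci0*cer.  Cluster states are not reset by
a spike.  Trials start at stimulus onset with ci = ci0, cer = 1 and all
clusters closed in 0_1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cluster import ClusterStats, cluster_stats, exit_rates, open_counts
from .params import ModelParams

__all__ = [
    "SpikeTrain",
    "LangevinCoefficients",
    "puff_current",
    "simulate_two_component",
    "simulate_langevin",
    "bifurcation_permeability",
    "langevin_coefficients",
    "buffer_scaling",
]

DEFAULT_DT = 1e-2


@dataclass
class SpikeTrain:
    """Spike times of one trial, measured from stimulus onset t0."""

    spike_times: np.ndarray
    t0: float = 0.0
    t_end: float = 0.0
    seed: int = 0
    scheme: str = ""
    traj_t: np.ndarray | None = field(default=None, repr=False)
    traj_ci: np.ndarray | None = field(default=None, repr=False)
    traj_cer: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and (np.any(np.diff(st) <= 0) or st[0] <= self.t0):
            raise ValueError("spike times must be strictly increasing and > t0")
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def puff_current(state, open_counts_per_cluster, params: ModelParams) -> float:
    """Instantaneous puff flux p * cer * sum_k x_k."""
    ci, cer = state
    if cer < 0:
        raise ValueError("cer must be >= 0")
    return params.p * cer * float(np.sum(open_counts_per_cluster))


def _trial_seeds(seed: int, n_trials: int) -> np.ndarray:
    """Deterministic per-trial substreams below 2**31."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n_trials, dtype=np.uint32) % np.uint32(2**31 - 1)).astype(np.int64)


@njit(cache=True)
def _langevin_trial(tau, p, K, ci0, cT, tau_er, eps, grid, mu_t, dx_t, dxp_t,
                    t_end, dt, seed, max_spikes, stride, traj_t, traj_ci, traj_cer):
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    ns = 0
    cer = 1.0
    ci = ci0
    sq = np.sqrt(dt)
    erdec = np.exp(-dt / tau_er)
    nst = int(t_end / dt)
    jtraj = 0
    for k in range(nst):
        if stride > 0 and k % stride == 0 and jtraj < traj_t.shape[0]:
            traj_t[jtraj] = k * dt
            traj_ci[jtraj] = ci
            traj_cer[jtraj] = cer
            jtraj += 1
        pc = p * cer
        pc2K = pc * pc * K
        mu = pc * K * np.interp(ci, grid, mu_t)
        D = pc2K * np.interp(ci, grid, dx_t)
        Dp = pc2K * np.interp(ci, grid, dxp_t)
        xi = np.random.normal()
        b = np.sqrt(2.0 * D)
        a1 = -(ci - ci0 * cer) / tau + mu + 0.5 * Dp
        cip = ci + dt * a1 + b * xi * sq
        mup = pc * K * np.interp(cip, grid, mu_t)
        Dpred = pc2K * np.interp(cip, grid, dx_t)
        a2 = -(cip - ci0 * cer) / tau + mup + 0.5 * pc2K * np.interp(cip, grid, dxp_t)
        cin = ci + 0.5 * dt * (a1 + a2) + 0.5 * (b + np.sqrt(2.0 * Dpred)) * xi * sq
        cer = 1.0 + (cer - 1.0) * erdec
        if cin >= cT:
            frac = (cT - ci) / (cin - ci) if cin > ci else 1.0
            if ns < max_spikes:
                spikes[ns] = (k + frac) * dt
                ns += 1
            cer = (1.0 - eps) * cer
            cin = ci0 * cer
        ci = cin
    return spikes[:ns], jtraj


@njit(cache=True)
def _hybrid_trial_K(tau, p, K, ci0, cT, tau_er, eps, base_rates, xcount,
                    lam_grid, lam_t, t_end, dt, seed, max_spikes,
                    stride, traj_t, traj_ci, traj_cer):
    np.random.seed(seed)
    nstates = base_rates.shape[0]
    states = np.full(K, nstates - 1, np.int64)  # all clusters start in 0_1
    spikes = np.empty(max_spikes)
    ns = 0
    cer = 1.0
    ci = ci0
    erdec = np.exp(-dt / tau_er)
    nst = int(t_end / dt)
    jtraj = 0
    for k in range(nst):
        if stride > 0 and k % stride == 0 and jtraj < traj_t.shape[0]:
            traj_t[jtraj] = k * dt
            traj_ci[jtraj] = ci
            traj_cer[jtraj] = cer
            jtraj += 1
        lam = np.interp(ci, lam_grid, lam_t)
        # exact jumps of each cluster within [0, dt); propensities frozen
        xint = 0.0  # integral of sum_k x_k over the step
        for q in range(K):
            s = states[q]
            tloc = 0.0
            while True:
                r = lam if s == nstates - 1 else base_rates[s]
                if r <= 0.0:
                    xint += (dt - tloc) * xcount[s]
                    break
                w = -np.log(np.random.random()) / r
                if tloc + w >= dt:
                    xint += (dt - tloc) * xcount[s]
                    break
                xint += w * xcount[s]
                tloc += w
                s = (s + 1) % nstates
            states[q] = s
        xbar = xint / dt
        cin = ci + dt * (-(ci - ci0 * cer) / tau + p * cer * xbar)
        cer = 1.0 + (cer - 1.0) * erdec
        if cin >= cT:
            frac = (cT - ci) / (cin - ci) if cin > ci else 1.0
            if ns < max_spikes:
                spikes[ns] = (k + frac) * dt
                ns += 1
            cer = (1.0 - eps) * cer
            cin = ci0 * cer
        ci = cin
    return spikes[:ns], jtraj


def _run_trials(kernel_args_fn, params, t_end, dt, seed, n_trials, scheme,
                max_spikes, store_traj, traj_stride):
    if dt > params.tau / 10:
        warnings.warn(
            f"dt={dt} is coarse relative to tau={params.tau}; threshold "
            "crossings may be missed -- refine dt"
        )
    seeds = _trial_seeds(seed, n_trials)
    nst = int(t_end / dt)
    ntr_pts = (nst // traj_stride + 1) if store_traj else 0
    trains = []
    for i in range(n_trials):
        tt = np.empty(ntr_pts)
        tci = np.empty(ntr_pts)
        tcer = np.empty(ntr_pts)
        stride = traj_stride if store_traj else 0
        spikes, jt = kernel_args_fn(int(seeds[i]), stride, tt, tci, tcer)
        trains.append(
            SpikeTrain(
                spike_times=spikes,
                t_end=t_end,
                seed=int(seeds[i]),
                scheme=scheme,
                traj_t=tt[:jt] if store_traj else None,
                traj_ci=tci[:jt] if store_traj else None,
                traj_cer=tcer[:jt] if store_traj else None,
            )
        )
    return trains


def simulate_langevin(
    params: ModelParams,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    n_trials: int = 1,
    stats: ClusterStats | None = None,
    max_spikes: int = 100_000,
    store_traj: bool = False,
    traj_stride: int = 100,
):
    """Langevin trials; returns a list of SpikeTrain."""
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    grid = stats.ci_grid
    mu_t = stats.mu_table
    dx_t = stats.beta * stats.dx_table
    dxp_t = np.gradient(dx_t, grid)

    def kernel(s, stride, tt, tci, tcer):
        return _langevin_trial(
            params.tau, params.p, float(params.n_clusters), params.ci0,
            params.c_threshold, params.tau_er, params.eps,
            grid, mu_t, dx_t, dxp_t, float(t_end), float(dt), s,
            max_spikes, stride, tt, tci, tcer,
        )

    return _run_trials(kernel, params, t_end, dt, seed, n_trials,
                       "langevin-heun", max_spikes, store_traj, traj_stride)


def simulate_two_component(
    params: ModelParams,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    n_trials: int = 1,
    max_spikes: int = 100_000,
    store_traj: bool = False,
    traj_stride: int = 100,
):
    """Hybrid (exact cluster jumps + Euler) trials; returns SpikeTrains."""
    cp = params.cluster
    base = exit_rates(cp, 0.0)  # opening entry (last) is replaced per step
    xcount = open_counts(cp)
    lam_grid = np.linspace(0.0, 1.0, 2001)
    lam_t = np.array([cp.rate_of_ci(c) for c in lam_grid])

    def kernel(s, stride, tt, tci, tcer):
        return _hybrid_trial_K(
            params.tau, params.p, params.n_clusters, params.ci0,
            params.c_threshold, params.tau_er, params.eps,
            base, xcount, lam_grid, lam_t, float(t_end), float(dt), s,
            max_spikes, stride, tt, tci, tcer,
        )

    return _run_trials(kernel, params, t_end, dt, seed, n_trials,
                       "hybrid-euler-ssa", max_spikes, store_traj, traj_stride)


def bifurcation_permeability(params: ModelParams, stats: ClusterStats | None = None) -> float:
    """Permeability p_bif separating mean-driven from excitable firing.

    p_bif = (cT - ci0) / (tau * K * mu_x(cT)); the model (at full store)
    is mean-driven iff p > p_bif.
    """
    if stats is None:
        stats = cluster_stats(params.cluster)
    mux = float(stats.mu_x(params.c_threshold))
    if mux <= 0:
        raise ValueError("mu_x(cT) = 0: no puff drive at threshold, no spiking")
    return (params.c_threshold - params.ci0) / (params.tau * params.n_clusters * mux)


@dataclass(frozen=True)
class LangevinCoefficients:
    """Coefficient bundle of the diffusion approximation."""

    params: ModelParams
    stats: ClusterStats

    def mu(self, ci, cer=1.0):
        return self.params.p * cer * self.params.n_clusters * self.stats.mu_x(ci)

    def D(self, ci, cer=1.0):
        return (self.params.p * cer) ** 2 * self.params.n_clusters * self.stats.D_x(ci)

    def D_prime(self, ci, cer=1.0):
        return (self.params.p * cer) ** 2 * self.params.n_clusters * self.stats.D_x_prime(ci)

    def f(self, ci, cer=1.0):
        return -(ci - self.params.ci0 * cer) / self.params.tau + self.mu(ci, cer)

    def g(self, cer):
        return -(cer - 1.0) / self.params.tau_er


def langevin_coefficients(params: ModelParams, stats: ClusterStats | None = None) -> LangevinCoefficients:
    if stats is None:
        stats = cluster_stats(params.cluster, params.buffer)
    return LangevinCoefficients(params, stats)


def buffer_scaling(stats: ClusterStats, b_total: float, k_star: float) -> ClusterStats:
    """Apply the fast-buffer noise reduction D_x -> beta * D_x."""
    if b_total < 0 or k_star <= 0:
        raise ValueError("require b_total >= 0 and k_star > 0")
    return stats.with_beta(1.0 / (1.0 + b_total / k_star))
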