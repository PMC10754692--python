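"""Cyclic Markov-chain kinetics of a single IP3R cluster.

The chain visits, in order, the open states N, N-1, ..., 1 (the label is
the number of open channels), then the refractory states 0_M, ..., 0_1,
and reopens 0_1 -> N with the ci-dependent rate lambda(ci).  From the
stationary distribution of the chain we obtain the mean open-channel
count mu_x(ci) and, from the integrated autocovariance, the noise
intensity D_x(ci) that enter the Langevin description of the puff
current.  Both are algebraic quantities of the generator matrix; no
closed forms are assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .params import BufferParams, ClusterParams

__all__ = [
    "ClusterGenerator",
    "ClusterStats",
    "build_generator",
    "stationary_distribution",
    "mean_open_channels",
    "noise_intensity",
    "buffer_factor",
    "cluster_stats",
    "simulate_cluster_ssa",
]


@dataclass(frozen=True)
class ClusterGenerator:
    """Rate matrix W (columns sum to zero) over the ordered cluster states."""

    states: tuple
    W: np.ndarray
    open_count: np.ndarray

    def __post_init__(self):
        colsums = self.W.sum(axis=0)
        if not np.allclose(colsums, 0.0, atol=1e-9):
            raise ValueError("generator columns must sum to zero")


def state_labels(params: ClusterParams) -> tuple:
    N, M = params.n_open, params.n_refractory
    return tuple(str(n) for n in range(N, 0, -1)) + tuple(
        f"0{m}" for m in range(M, 0, -1)
    )


def open_counts(params: ClusterParams) -> np.ndarray:
    N, M = params.n_open, params.n_refractory
    return np.array([float(n) for n in range(N, 0, -1)] + [0.0] * M)


def exit_rates(params: ClusterParams, ci: float) -> np.ndarray:
    """Exit rate of each state along the cycle (the chain is unidirectional)."""
    N, M = params.n_open, params.n_refractory
    lam = params.rate_of_ci(ci)
    rates = np.empty(N + M)
    for idx, n in enumerate(range(N, 0, -1)):
        rates[idx] = n * params.k_minus if params.closing_rate_rule == "proportional" else params.k_minus
    rates[N : N + M - 1] = params.k_plus  # 0_M ... 0_2
    rates[N + M - 1] = lam  # 0_1 -> N
    return rates


def build_generator(params: ClusterParams, ci: float) -> ClusterGenerator:
    """Assemble the cyclic generator matrix at cytosolic concentration ci."""
    if ci < 0:
        raise ValueError("ci must be >= 0")
    n = params.n_states
    rates = exit_rates(params, ci)
    W = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n  # successor along the cycle; 0_1 wraps to state N
        W[j, i] += rates[i]
        W[i, i] -= rates[i]
    return ClusterGenerator(states=state_labels(params), W=W, open_count=open_counts(params))


def stationary_distribution(gen: ClusterGenerator) -> np.ndarray:
    """Probability vector p solving W p = 0, sum(p) = 1.

    A chain whose opening rate vanishes is reducible: all mass collects
    in the last refractory state; that degenerate vector is returned
    with a warning.
    """
    n = gen.W.shape[0]
    if gen.W[:, n - 1].max() <= 0.0 and abs(gen.W[n - 1, n - 1]) <= 0.0:
        warnings.warn("opening rate is zero; chain is absorbed in the closed state")
        p = np.zeros(n)
        p[n - 1] = 1.0
        return p
    A = gen.W.copy()
    A[-1, :] = 1.0  # replace one redundant balance row by normalization
    b = np.zeros(n)
    b[-1] = 1.0
    p = np.linalg.solve(A, b)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def mean_open_channels(params: ClusterParams, ci: float) -> float:
    """Stationary mean number of open channels mu_x(ci)."""
    gen = build_generator(params, ci)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stationary_distribution(gen)
    return float(gen.open_count @ p)


def noise_intensity(params: ClusterParams, ci: float) -> float:
    """Integrated autocovariance D_x(ci) = int_0^inf <dx(t) dx(0)> dt.

    Solves the singular system W y = -(x - mu_x) * p with the constraint
    sum(y) = 0 (a bordered/Lagrange solve), then D_x = x . y.
    """
    gen = build_generator(params, ci)
    if params.rate_of_ci(ci) == 0.0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stationary_distribution(gen)
    x = gen.open_count
    mu = x @ p
    n = len(x)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gen.W
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.zeros(n + 1)
    b[:n] = -(x - mu) * p
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular D_x solve at ci={ci}: {err}") from err
    resid = gen.W @ sol[:n] - b[:n]
    if np.max(np.abs(resid)) > 1e-10 * max(1.0, np.max(np.abs(b))):
        raise np.linalg.LinAlgError(f"D_x solve did not converge at ci={ci}")
    Dx = float(x @ sol[:n])
    return max(Dx, 0.0)


def buffer_factor(buffer: BufferParams) -> float:
    """Noise-reduction factor beta of a fast buffer, 1/(1 + bT/K*)."""
    return buffer.beta


@dataclass(frozen=True)
class ClusterStats:
    """Tabulated mu_x(ci) and D_x(ci) plus the fast-buffer factor beta.

    The tables are dense enough (default 4000 points on [0, ci_max])
    that linear interpolation is accurate to ~1e-8; ci below zero maps
    to zero activity and ci above the table end saturates at the last
    value.
    """

    ci_grid: np.ndarray
    mu_table: np.ndarray
    dx_table: np.ndarray
    beta: float = 1.0

    def mu_x(self, ci):
        return np.interp(ci, self.ci_grid, self.mu_table, left=0.0)

    def D_x(self, ci):
        return self.beta * np.interp(ci, self.ci_grid, self.dx_table, left=0.0)

    def D_x_prime(self, ci):
        grad = np.gradient(self.dx_table, self.ci_grid)
        return self.beta * np.interp(ci, self.ci_grid, grad, left=0.0)

    def with_beta(self, beta: float) -> "ClusterStats":
        return ClusterStats(self.ci_grid, self.mu_table, self.dx_table, beta)


def cluster_stats(
    params: ClusterParams,
    buffer: BufferParams | None = None,
    ci_max: float = 1.0,
    n_points: int = 4000,
) -> ClusterStats:
    """Tabulate mu_x and D_x over a ci grid for fast repeated evaluation."""
    grid = np.linspace(0.0, ci_max, n_points)
    mu = np.empty(n_points)
    dx = np.empty(n_points)
    for i, c in enumerate(grid):
        if params.rate_of_ci(c) <= 0.0:
            mu[i] = dx[i] = 0.0
        else:
            mu[i] = mean_open_channels(params, c)
            dx[i] = noise_intensity(params, c)
    beta = buffer.beta if buffer is not None else 1.0
    return ClusterStats(grid, mu, dx, beta)


@njit(cache=True)
def _ssa_core(exit_rates, start_state, t_end, seed, max_events):
    """Exact jump chain of one unidirectional cycle with frozen rates."""
    np.random.seed(seed)
    n = exit_rates.shape[0]
    times = np.empty(max_events)
    states = np.empty(max_events, np.int64)
    s = start_state
    t = 0.0
    k = 0
    times[k] = 0.0
    states[k] = s
    k += 1
    while t < t_end and k < max_events:
        r = exit_rates[s]
        if r <= 0.0:
            break
        t += -np.log(np.random.random()) / r
        if t >= t_end:
            break
        s = (s + 1) % n
        times[k] = t
        states[k] = s
        k += 1
    return times[:k], states[:k]


def simulate_cluster_ssa(
    params: ClusterParams,
    K: int,
    ci_source,
    t_end: float,
    seed: int = 0,
    max_events_per_cluster: int = 2_000_000,
):
    """Gillespie trajectories of K independent clusters.

    ci_source may be a frozen number or a callable t -> ci; with a
    callable the opening propensity is refreshed at every jump of the
    respective cluster (the chain is unidirectional, so only the 0_1
    state consults lambda).

    Returns a list of (times, state_indices) pairs, one per cluster;
    state index 0 is the fully open state N, the last index is 0_1.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    n = params.n_states
    start = n - 1  # all clusters start closed in 0_1
    out = []
    if callable(ci_source):
        rng = np.random.default_rng(seed)
        for k in range(K):
            t, s = 0.0, start
            times, states = [0.0], [start]
            while t < t_end:
                rates = exit_rates(params, float(ci_source(t)))
                r = rates[s]
                if r <= 0.0:
                    break
                t += rng.exponential(1.0 / r)
                if t >= t_end:
                    break
                s = (s + 1) % n
                times.append(t)
                states.append(s)
            out.append((np.array(times), np.array(states, dtype=np.int64)))
    else:
        rates = exit_rates(params, float(ci_source))
        for k in range(K):
            times, states = _ssa_core(rates, start, float(t_end), seed + k, max_events_per_cluster)
            out.append((times, states))
    return out


def occupancy_from_ssa(traj: Sequence, n_states: int, t_end: float) -> np.ndarray:
    """Time-fraction spent in each state, averaged over clusters."""
    occ = np.zeros(n_states)
    total = 0.0
    for times, states in traj:
        bounds = np.append(times, t_end)
        dt = np.diff(bounds)
        np.add.at(occ, states, dt)
        total += t_end
    return occ / total


def ssa_mean_open(traj: Sequence, open_count: np.ndarray, t_end: float) -> float:
    """Time-averaged open-channel count per cluster from SSA output."""
    occ = occupancy_from_ssa(traj, len(open_count), t_end)
    return float(open_count @ occ)
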