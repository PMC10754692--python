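"""Interspike-interval and spike-train statistics.

The first interval T0 = t1 - t0 measures the latency from stimulus
onset to the first spike and is bookkept separately -- it is not an ISI.
Stationary summaries (mean, CV, serial correlations, spectra) are
computed after truncating the transient; the default truncation drops
the first ceil(2 * n_tr) intervals, with n_tr taken from the exponential
transient fit, mirroring the experimental procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import welch

from .simulate import SpikeTrain

__all__ = [
    "ISISequence",
    "StationaryStats",
    "TransientFit",
    "intervals_from_spikes",
    "serial_correlation",
    "correlation_decay_fit",
    "spike_train_spectrum",
    "transient_fit",
    "ensemble_relaxation",
    "conditional_next_interval",
    "stationary_stats",
    "shuffle_intervals",
]


@dataclass
class ISISequence:
    """Interval sequence with the first (onset) interval kept apart."""

    intervals: np.ndarray
    first_interval: float | None = None
    t0: float = 0.0
    seed: int | None = None
    trial_id: int | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        if iv.size and np.any(iv <= 0):
            raise ValueError("all intervals must be > 0")
        self.intervals = iv

    def __len__(self):
        return len(self.intervals)

    def with_first(self) -> np.ndarray:
        """Full sequence T0, T1, ... as fitted during the transient."""
        if self.first_interval is None:
            return self.intervals
        return np.concatenate([[self.first_interval], self.intervals])


@dataclass
class StationaryStats:
    mean: float
    cv: float
    scc: np.ndarray
    n_corr: float | None = None
    freq: np.ndarray | None = None
    spectrum: np.ndarray | None = None
    delta_cv: float | None = None
    n_intervals: int = 0


@dataclass
class TransientFit:
    T0_fit: float
    T_inf_fit: float
    n_tr_fit: float
    delta_T_fit: float
    tau_eff: float | None = None
    residual: float = np.nan
    success: bool = True


def intervals_from_spikes(train: SpikeTrain) -> ISISequence:
    """Differences of successive spike times; T0 = t1 - t0 kept separate."""
    st = train.spike_times
    if np.any(np.diff(st) <= 0):
        raise ValueError("spike times must be strictly increasing")
    if len(st) < 2:
        return ISISequence(np.empty(0), first_interval=st[0] - train.t0 if len(st) else None,
                           t0=train.t0, seed=train.seed, flags={"too_few_spikes": True})
    return ISISequence(
        intervals=np.diff(st),
        first_interval=st[0] - train.t0,
        t0=train.t0,
        seed=train.seed,
    )


def serial_correlation(seq, k_max: int = 10, truncate: int = 0) -> np.ndarray:
    """Serial correlation coefficients rho_k, k = 0..k_max.

    rho_k = <dT_{i+k} dT_i> / <dT_i^2> over the stationary segment after
    dropping the first ``truncate`` intervals.  The biased (1/n)
    covariance normalization is used so the sequence is the Fourier pair
    of a nonnegative spectrum.
    """
    x = seq.intervals if isinstance(seq, ISISequence) else np.asarray(seq, float)
    x = x[truncate:]
    n = len(x)
    if n < k_max + 2:
        raise ValueError("not enough intervals after truncation")
    d = x - x.mean()
    denom = float(d @ d) / n
    if denom == 0:
        raise ZeroDivisionError("zero interval variance: SCC undefined")
    rho = np.empty(k_max + 1)
    for k in range(k_max + 1):
        rho[k] = (d[k:] @ d[: n - k]) / n / denom
    return rho


def correlation_decay_fit(rho: np.ndarray):
    """Fit rho_k ~ rho_1 * exp(-(k-1)/n_corr) for k >= 1 and check the
    sum rule sum_k rho_k >= -1/2 and the bound n_corr >= -1/ln(1+2*rho_1).

    Returns a dict with n_corr (None when rho_1 >= 0), the bound, and
    booleans for the two inequalities.
    """
    rho = np.asarray(rho, dtype=float)
    rho1 = rho[1]
    out = {
        "rho1": float(rho1),
        "sum_rho": float(rho[1:].sum()),
        "sum_rule_ok": bool(rho[1:].sum() >= -0.5),
        "n_corr": None,
        "n_corr_bound": None,
        "bound_ok": None,
    }
    if rho1 >= 0:
        out["flag"] = "rho1 >= 0: geometric decay fit skipped"
        return out
    k = np.arange(1, len(rho))
    y = rho[1:]
    # least squares on n_corr only (amplitude pinned at rho_1)
    from scipy.optimize import minimize_scalar

    def sse(log_nc):
        nc = np.exp(log_nc)
        return float(np.sum((y - rho1 * np.exp(-(k - 1) / nc)) ** 2))

    res = minimize_scalar(sse, bounds=(np.log(1e-2), np.log(1e3)), method="bounded")
    nc = float(np.exp(res.x))
    out["n_corr"] = nc
    if -0.5 <= rho1 < 0:
        bound = -1.0 / np.log(1.0 + 2.0 * rho1)
        out["n_corr_bound"] = float(bound)
        out["bound_ok"] = bool(nc >= bound - 1e-9) if np.isfinite(bound) else None
    return out


def spike_train_spectrum(
    trains,
    bin_fraction: float = 0.05,
    truncate_time: float = 0.0,
    nperseg: int | None = None,
):
    """Welch spectrum S(f) of the binned delta-spike train.

    The spike train z(t) = sum_i delta(t - t_i) is binned at
    ``bin_fraction`` of the mean ISI; Hann windows with 50% overlap.
    Returns (f, S, s_low, s_pred) where s_low averages S over the lowest
    resolvable decade and s_pred = r0 * CV^2 * (1 + 2 * sum_k rho_k) is
    the renewal-theory low-frequency limit computed from the same data.
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    all_isis = []
    spikes_list = []
    for tr in trains:
        st = tr.spike_times[tr.spike_times >= truncate_time]
        spikes_list.append(st)
        if len(st) > 2:
            all_isis.append(np.diff(st))
    isis = np.concatenate(all_isis)
    mean_isi = isis.mean()
    t_end = max(tr.t_end for tr in trains)
    duration = t_end - truncate_time
    if duration < 30 * mean_isi:
        raise ValueError("stationary segment too short for a spectrum")
    dt = bin_fraction * mean_isi
    nbins = int(duration / dt)
    psds = []
    for st in spikes_list:
        counts, _ = np.histogram(st, bins=nbins, range=(truncate_time, truncate_time + nbins * dt))
        z = counts / dt
        nps = nperseg or min(nbins // 4, 2 ** int(np.log2(max(nbins // 4, 16))))
        # mean removal kills the DC delta of the rate, whose Hann-window
        # leakage would otherwise swamp the lowest bins
        f, pxx = welch(z, fs=1.0 / dt, window="hann", nperseg=nps, noverlap=nps // 2,
                       detrend="constant")
        psds.append(pxx)
    # welch returns the one-sided density; the point-process convention
    # S(f) = lim <|z~(f)|^2>/T is two-sided, hence the factor 1/2
    S = np.mean(psds, axis=0) / 2.0
    r0 = 1.0 / mean_isi
    cv = isis.std() / mean_isi
    rho = serial_correlation(isis, k_max=min(20, len(isis) // 10))
    s_pred = r0 * cv**2 * (1.0 + 2.0 * rho[1:].sum())
    # skip the two lowest bins (suppressed by per-segment mean removal)
    fpos = f[2:]
    lowmask = fpos <= f[1] * 10
    s_low = float(S[2:][lowmask].mean())
    return f, S, s_low, float(s_pred)


def _exp_transient(i, T0, T_inf, n_tr):
    return T_inf - (T_inf - T0) * np.exp(-i / n_tr)


def transient_fit(sequences, mode: str = "single", max_intervals: int | None = None) -> TransientFit:
    """Fit T_i = T_inf - (T_inf - T0) exp(-i / n_tr) with positive parameters.

    mode="single" fits one realization; mode="ensemble_mean" averages the
    interval sequence index-wise across trials first.  The first
    (onset) interval enters as index 0.  Failures are returned as a
    flagged record, not raised.
    """
    if isinstance(sequences, ISISequence):
        sequences = [sequences]
    seqs = [s.with_first() for s in sequences]
    if mode == "ensemble_mean":
        nmin = min(len(s) for s in seqs)
        y = np.mean([s[:nmin] for s in seqs], axis=0)
    else:
        if len(seqs) != 1:
            raise ValueError("single mode expects exactly one sequence")
        y = seqs[0]
    if max_intervals:
        y = y[:max_intervals]
    if len(y) < 4:
        return TransientFit(np.nan, np.nan, np.nan, np.nan, success=False)
    i = np.arange(len(y), dtype=float)
    best = None
    ymax, y0 = float(y.max()), float(max(y[0], 1e-6))
    starts = [
        (y0, ymax, 3.0),
        (0.5 * y0, 1.2 * ymax, 1.5),
        (y0, float(np.mean(y)), 6.0),
    ]
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _exp_transient, i, y, p0=p0,
                bounds=([0.0, 1e-9, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            resid = float(np.sum((_exp_transient(i, *popt) - y) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        except Exception:
            continue
    if best is None:
        return TransientFit(np.nan, np.nan, np.nan, np.nan, success=False)
    (T0, T_inf, n_tr), resid = best
    return TransientFit(
        T0_fit=T0, T_inf_fit=T_inf, n_tr_fit=n_tr,
        delta_T_fit=T_inf - T0, residual=resid, success=True,
    )


def ensemble_relaxation(trials, dt_bin: float = 1.0):
    """Instantaneous rate r(t), ensemble mean <cer(t)>, and tau_eff.

    All trials must carry sampled (t, cer) trajectories and share the
    onset/duration.  tau_eff is fit from
    <cer(t)> ~= cer_inf + (1 - cer_inf) exp(-t/tau_eff).
    Returns a dict with t_bins, rate, t_traj, mean_cer, tau_eff,
    cer_inf and a flags dict.
    """
    flags = {}
    if len(trials) < 50:
        warnings.warn("fewer than 50 trials: tau_eff estimate is unreliable")
        flags["few_trials"] = True
    t_end = trials[0].t_end
    edges = np.arange(0.0, t_end + dt_bin, dt_bin)
    counts = np.zeros(len(edges) - 1)
    for tr in trials:
        c, _ = np.histogram(tr.spike_times, bins=edges)
        counts += c
    rate = counts / (len(trials) * dt_bin)
    if trials[0].traj_t is None:
        raise ValueError("trials carry no trajectories; rerun with store_traj=True")
    npts = min(len(tr.traj_t) for tr in trials)
    t_traj = trials[0].traj_t[:npts]
    mean_cer = np.mean([tr.traj_cer[:npts] for tr in trials], axis=0)
    tau_eff = cer_inf = None
    if np.allclose(mean_cer, 1.0, atol=1e-12):
        flags["no_depletion"] = True
    else:
        def model(t, ci_, te):
            return ci_ + (1.0 - ci_) * np.exp(-t / te)
        try:
            popt, _ = curve_fit(model, t_traj, mean_cer,
                                p0=[float(mean_cer[-1]), t_end / 5],
                                bounds=([0.0, 1e-6], [1.0, np.inf]), maxfev=20000)
            cer_inf, tau_eff = float(popt[0]), float(popt[1])
        except Exception:
            flags["fit_failed"] = True
    return {
        "t_bins": 0.5 * (edges[1:] + edges[:-1]),
        "rate": rate,
        "t_traj": t_traj,
        "mean_cer": mean_cer,
        "tau_eff": tau_eff,
        "cer_inf": cer_inf,
        "flags": flags,
    }


def conditional_next_interval(seq, n_bins: int = 10, min_per_bin: int = 10):
    """Binned conditional mean <T_{i+1} | T_i> with equal-occupancy bins."""
    x = seq.intervals if isinstance(seq, ISISequence) else np.asarray(seq, float)
    if len(x) < 200:
        raise ValueError("need at least 200 intervals")
    Ti, Tnext = x[:-1], x[1:]
    qs = np.quantile(Ti, np.linspace(0, 1, n_bins + 1))
    centers, means, counts = [], [], []
    for a, b in zip(qs[:-1], qs[1:]):
        m = (Ti >= a) & (Ti <= b if b == qs[-1] else Ti < b)
        if m.sum() < min_per_bin:
            continue
        centers.append(float(Ti[m].mean()))
        means.append(float(Tnext[m].mean()))
        counts.append(int(m.sum()))
    if len(centers) < n_bins:
        warnings.warn("sparse bins merged/dropped in conditional mean")
    return np.array(centers), np.array(means), np.array(counts)


def shuffle_intervals(seq: ISISequence, seed: int = 0) -> ISISequence:
    """Random permutation of the intervals (decorrelates, preserves the
    marginal distribution exactly)."""
    rng = np.random.default_rng(seed)
    return ISISequence(rng.permutation(seq.intervals),
                       first_interval=seq.first_interval, t0=seq.t0, seed=seed)


def stationary_stats(
    seq,
    truncate: int | str = "auto",
    k_max: int = 10,
    cv_reference: float | None = None,
) -> StationaryStats:
    """Stationary summary of one interval sequence.

    truncate="auto" drops ceil(2 * n_tr) intervals using the transient
    fit (counting from the onset interval); an integer drops that many.
    """
    if not isinstance(seq, ISISequence):
        seq = ISISequence(np.asarray(seq, float))
    if truncate == "auto":
        tf = transient_fit(seq)
        truncate = int(np.ceil(2 * tf.n_tr_fit)) if tf.success and np.isfinite(tf.n_tr_fit) else 0
        truncate = min(truncate, max(len(seq) - 8, 0))
    x = seq.intervals[truncate:]
    mean = float(x.mean())
    cv = float(x.std() / mean)
    rho = serial_correlation(x, k_max=min(k_max, len(x) - 2))
    decay = correlation_decay_fit(rho)
    dcv = (cv - cv_reference) / cv_reference if cv_reference else None
    return StationaryStats(
        mean=mean, cv=cv, scc=rho, n_corr=decay["n_corr"],
        delta_cv=dcv, n_intervals=len(x),
    )
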