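"""Synthetic HEK-like ISI sequences.

Experimentally observed sequences show an exponential transient of the
mean interval and approximately inverse-Gaussian stationary intervals.
The generator draws interval i from an inverse Gaussian whose mean
follows T_inf - (T_inf - T0) * exp(-i / n_tr) and whose coefficient of
variation is fixed at ``cv``; index 0 plays the role of the onset
interval.  These fixtures reproduce the statistical structure the
analysis relies on but none of the biological nuisance features of real
recordings (drift, missed spikes, cell-to-cell baseline variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import ISISequence

__all__ = ["FixtureSpec", "generate_fixture", "generate_battery"]


@dataclass(frozen=True)
class FixtureSpec:
    T0: float = 60.0
    T_inf: float = 180.0
    n_tr: float = 3.5
    cv: float = 0.2
    n_intervals: int = 25
    noise: str = "inverse_gaussian"
    seed: int = 0

    def __post_init__(self):
        if min(self.T0, self.T_inf, self.n_tr) <= 0:
            raise ValueError("T0, T_inf, n_tr must be positive")
        if not 0.0 <= self.cv < 1.5:
            raise ValueError("cv must lie in [0, 1.5)")
        if self.noise not in ("inverse_gaussian",):
            raise ValueError(f"unknown noise family {self.noise!r}")


def generate_fixture(spec: FixtureSpec) -> ISISequence:
    """One synthetic sequence; reproducible under the spec seed."""
    i = np.arange(spec.n_intervals + 1, dtype=float)  # index 0 = onset interval
    mean_i = spec.T_inf - (spec.T_inf - spec.T0) * np.exp(-i / spec.n_tr)
    if spec.cv == 0.0:
        draws = mean_i
    else:
        # scipy invgauss(mu, scale): mean = mu*scale, CV^2 = mu
        rng = np.random.default_rng(spec.seed)
        mu_shape = spec.cv**2
        draws = sps.invgauss.rvs(mu_shape, scale=mean_i / mu_shape, random_state=rng)
    return ISISequence(intervals=draws[1:], first_interval=float(draws[0]),
                       seed=spec.seed, flags={"synthetic": True})


def generate_battery(
    n_cells: int = 24,
    seed: int = 0,
    mean_n_tr: float = 3.5,
    sd_n_tr: float = 1.9,
    mean_delta_T: float = 200.0,
    sd_delta_T: float = 80.0,
    mean_T0: float = 60.0,
    cv: float = 0.2,
    n_intervals: int = 25,
):
    """A battery of heterogeneous sequences emulating a population of
    stimulated cells (cell-to-cell spread of n_tr and DeltaT)."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_cells):
        n_tr = max(rng.normal(mean_n_tr, sd_n_tr), 0.8)
        dT = max(rng.normal(mean_delta_T, sd_delta_T), 20.0)
        T0 = max(rng.normal(mean_T0, 0.2 * mean_T0), 10.0)
        specs.append(FixtureSpec(
            T0=T0, T_inf=T0 + dT, n_tr=n_tr, cv=cv,
            n_intervals=n_intervals, seed=int(rng.integers(2**31 - 1)),
        ))
    return [generate_fixture(s) for s in specs], specs
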