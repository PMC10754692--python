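import numpy as np
import pytest

import caspike as cs


@pytest.fixture(scope="session")
def default_params():
    return cs.ModelParams()


@pytest.fixture(scope="session")
def default_stats(default_params):
    """Tabulated cluster statistics; shared across the session because
    tabulation solves ~8000 small linear systems."""
    return cs.cluster_stats(default_params.cluster, default_params.buffer)


@pytest.fixture(scope="session")
def excitable_params(default_params):
    return default_params.with_(tau=1.0, p=0.06)


def collect_isis(trains, drop=0):
    out = []
    for tr in trains:
        iv = np.diff(tr.spike_times)
        if len(iv) > drop:
            out.append(iv[drop:])
    return np.concatenate(out) if out else np.empty(0)


@pytest.fixture(scope="session")
def adaptive_ensemble(default_params, default_stats):
    """A moderate ensemble at the reference adaptive parameter set
    (tau=5 s, p=0.015, tau_er=300 s, eps=0.03), with trajectories."""
    return cs.simulate_langevin(
        default_params, t_end=2500.0, seed=42, n_trials=120,
        stats=default_stats, store_traj=True, traj_stride=100,
    )
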