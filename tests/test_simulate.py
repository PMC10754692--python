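"""Simulator contracts: reset/depletion rules, determinism, convergence,
bifurcation condition, Langevin coefficient scalings."""

import numpy as np
import pytest

import caspike as cs
from conftest import collect_isis


def test_puff_current_values(default_params):
    assert cs.puff_current((0.3, 1.0), np.zeros(10), default_params) == 0.0
    p = default_params.with_(p=0.015)
    assert cs.puff_current((0.3, 1.0), np.array([4, 6]), p) == pytest.approx(0.15)


def test_identical_seeds_identical_spike_trains(default_params, default_stats):
    a = cs.simulate_langevin(default_params, 500.0, seed=3, n_trials=2, stats=default_stats)
    b = cs.simulate_langevin(default_params, 500.0, seed=3, n_trials=2, stats=default_stats)
    for x, y in zip(a, b):
        assert np.array_equal(x.spike_times, y.spike_times)
    h1 = cs.simulate_two_component(default_params, 300.0, seed=3, n_trials=1)
    h2 = cs.simulate_two_component(default_params, 300.0, seed=3, n_trials=1)
    assert np.array_equal(h1[0].spike_times, h2[0].spike_times)


def test_store_depletion_rule_and_bounds(default_params, default_stats):
    """cer stays in (0, 1]; across each spike it drops by the factor
    (1 - eps) applied to the pre-spike value."""
    tr = cs.simulate_langevin(default_params.with_(eps=0.2), 600.0, seed=8,
                              n_trials=1, stats=default_stats,
                              store_traj=True, traj_stride=1)[0]
    cer = tr.traj_cer
    assert np.all(cer > 0) and np.all(cer <= 1.0 + 1e-12)
    dt = tr.traj_t[1] - tr.traj_t[0]
    for t_spike in tr.spike_times[:10]:
        k = int(t_spike / dt)
        before, after = cer[k], cer[k + 1]
        # one step spans relaxation + the depletion kick
        assert after / before == pytest.approx(0.8, abs=0.01)


def test_no_adaptation_keeps_store_full_and_train_renewal(default_params, default_stats):
    trains = cs.simulate_langevin(default_params.with_(eps=0.0), 3000.0, seed=12,
                                  n_trials=30, stats=default_stats,
                                  store_traj=True, traj_stride=50)
    assert all(np.allclose(tr.traj_cer, 1.0) for tr in trains)
    isis = collect_isis(trains, drop=2)
    rho1 = cs.serial_correlation(isis, k_max=1)[1]
    assert abs(rho1) < 3.0 / np.sqrt(len(isis))


def test_adaptive_train_is_anticorrelated(adaptive_ensemble):
    isis = collect_isis(adaptive_ensemble, drop=8)
    rho1 = cs.serial_correlation(isis, k_max=1)[1]
    assert -0.5 < rho1 < 0.0


def test_first_interval_independent_of_adaptation_parameters(default_params, default_stats):
    """T0 only sees a full store, so its mean is invariant across
    (tau_er, eps) within Monte-Carlo error."""
    t0s = []
    for tau_er, eps in [(100.0, 0.01), (300.0, 0.03), (1000.0, 0.2)]:
        trains = cs.simulate_langevin(
            default_params.with_(tau_er=tau_er, eps=eps), 150.0, seed=77,
            n_trials=150, stats=default_stats)
        t0 = np.array([tr.spike_times[0] for tr in trains if tr.n_spikes])
        t0s.append((t0.mean(), t0.std() / np.sqrt(len(t0))))
    means = np.array([m for m, _ in t0s])
    ses = np.array([s for _, s in t0s])
    assert np.all(np.abs(means - means[0]) < 3 * np.hypot(ses, ses[0]))


def test_langevin_hybrid_agreement(default_params, default_stats):
    """Diffusion approximation vs exact cluster jumps: mean ISI and CV
    within 10% at the mean-driven reference parameters, eps=0."""
    p = default_params.with_(eps=0.0)
    lan = cs.simulate_langevin(p, 3500.0, seed=4, n_trials=15, stats=default_stats)
    hyb = cs.simulate_two_component(p, 3500.0, seed=4, n_trials=15)
    il, ih = collect_isis(lan, 3), collect_isis(hyb, 3)
    assert il.mean() == pytest.approx(ih.mean(), rel=0.10)
    assert il.std() / il.mean() == pytest.approx(ih.std() / ih.mean(), rel=0.10)


def test_langevin_dt_convergence(default_params, default_stats):
    p = default_params.with_(eps=0.0)
    coarse = collect_isis(cs.simulate_langevin(p, 2500.0, dt=1e-2, seed=6,
                                               n_trials=20, stats=default_stats), 2)
    fine = collect_isis(cs.simulate_langevin(p, 2500.0, dt=5e-3, seed=6,
                                             n_trials=20, stats=default_stats), 2)
    assert fine.mean() == pytest.approx(coarse.mean(), rel=0.01 + 3 * fine.std()
                                        / fine.mean() / np.sqrt(len(fine)))


def test_deterministic_drive_crossing_time(default_params):
    """With D == 0 and a constant supra-threshold drive the ISI equals
    the closed-form crossing time of the linear ODE."""
    mu0 = 0.2
    cp = cs.ClusterParams(n_open=1, n_refractory=1, k_minus=1e-12, k_plus=1e3,
                          opening_rate=lambda ci: 1e3)
    # mu_x ~= 1, D_x ~= 0: drive = p*K*1
    p = default_params.with_(p=mu0, n_clusters=1, eps=0.0, cluster=cp)
    st = cs.cluster_stats(cp)
    assert st.D_x(0.5) < 1e-6
    tr = cs.simulate_langevin(p, 60.0, dt=1e-3, seed=1, n_trials=1, stats=st)[0]
    tau, ci0, cT = p.tau, p.ci0, p.c_threshold
    # dc/dt = -(c - ci0)/tau + mu0 ; c(0)=ci0 -> t* = -tau*ln(1 - (cT-ci0)/(mu0*tau))
    t_exact = -tau * np.log(1.0 - (cT - ci0) / (mu0 * tau))
    isis = np.diff(tr.spike_times)
    assert isis.mean() == pytest.approx(t_exact, rel=2e-3)


def test_bifurcation_permeability_scalings(default_params, default_stats):
    p0 = cs.bifurcation_permeability(default_params, default_stats)
    assert cs.bifurcation_permeability(default_params.with_(tau=10.0), default_stats) == pytest.approx(p0 / 2)
    assert cs.bifurcation_permeability(default_params.with_(n_clusters=20), default_stats) == pytest.approx(p0 / 2)


def test_buffer_scan_permeability_consistency(default_params, default_stats):
    """The two quoted buffer-scan permeabilities are 1.05x and 0.95x the
    same bifurcation value (~0.1295 1/s at K=5, tau=1 s)."""
    p_bif = cs.bifurcation_permeability(default_params.with_(tau=1.0, n_clusters=5),
                                        default_stats)
    assert 0.136 / 1.05 == pytest.approx(0.123 / 0.95, rel=0.005)
    assert p_bif == pytest.approx(0.1295, rel=0.005)


def test_langevin_coefficient_scalings(default_params, default_stats):
    co = cs.langevin_coefficients(default_params, default_stats)
    ci = 0.4
    assert co.mu(ci, 1.0) == pytest.approx(2 * co.mu(ci, 0.5))
    assert co.D(ci, 1.0) == pytest.approx(4 * co.D(ci, 0.5))
    zero = cs.langevin_coefficients(default_params.with_(p=0.0), default_stats)
    assert zero.mu(ci) == 0.0 and zero.D(ci) == 0.0
    # leak vanishes at the reset point: f(ci0*cer, cer) = mu(ci0*cer, cer)
    for cer in (0.8, 1.0):
        assert co.f(default_params.ci0 * cer, cer) == pytest.approx(
            co.mu(default_params.ci0 * cer, cer))


def test_d_prime_matches_refined_finite_difference(default_params, default_stats):
    co = cs.langevin_coefficients(default_params, default_stats)
    ci = 0.37
    h = 1e-4 * ci
    fd = (co.D(ci + h) - co.D(ci - h)) / (2 * h)
    assert co.D_prime(ci) == pytest.approx(fd, rel=1e-3)


def test_buffer_scaling_leaves_mean_untouched(default_stats):
    scaled = cs.buffer_scaling(default_stats, 3.0, 1.0)
    assert scaled.beta == pytest.approx(0.25)
    assert scaled.mu_x(0.5) == default_stats.mu_x(0.5)
    assert scaled.D_x(0.5) == pytest.approx(0.25 * default_stats.D_x(0.5))
    same = cs.buffer_scaling(default_stats, 0.0, 1.0)
    assert same.D_x(0.5) == default_stats.D_x(0.5)
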