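# caspike

Stochastic modelling of IP₃-induced Ca²⁺ spiking with cumulative
depletion of the endoplasmic-reticulum (ER) store.

Many cell types translate a constant agonist stimulus into a sequence of
cytosolic Ca²⁺ spikes. After stimulus onset the interspike intervals
(ISIs) typically lengthen over a handful of spikes before becoming
stationary — *cumulative refractoriness* — and even the stationary
intervals remain negatively correlated. `caspike` implements an
adaptive integrate-and-fire model that explains both observations by one
mechanism: each spike expels a fraction ε of the ER Ca²⁺ content, which
is only slowly restored by store-operated Ca²⁺ entry.

The package is aimed at modellers of intracellular Ca²⁺ signalling and
at experimentalists who want to infer store-depletion parameters (τ_er,
ε) from a single measured ISI sequence.

## Model

Cytosolic concentration c_i (in units of the IP₃R activation constant
K_act) and store content c_er (relative to the full store) obey

    dc_i/dt  = −(c_i − c_i0·c_er)/τ + J_puff(c_i, c_er)
    dc_er/dt = −(c_er − 1)/τ_er − ε·c_er·Σ_i δ(t−t_i)

with a fire-and-reset rule: when c_i reaches the threshold c_T a spike
time t_i is recorded, c_er ← (1−ε)·c_er, and c_i is reset to c_i0·c_er.
The puff current J_puff = p·c_er·Σ_k x_k sums the open channels x_k of
K independent IP₃R clusters, each a cyclic Markov chain
(0₁ → N → N−1 → … → 1 → 0_M → … → 0₁) whose opening rate λ(c_i) is
Ca²⁺-dependent. Two simulators are provided:

* **hybrid** — exact Gillespie jumps of the cluster chains coupled to
  the c_i integration;
* **Langevin** — the diffusion approximation with drift
  μ = p·c_er·K·μ_x(c_i) and intensity D = (p·c_er)²·K·D_x(c_i), where
  μ_x and D_x follow algebraically from the chain generator.

On top of the simulators sit

* the **mean-adaptation theory**: the stationary firing rate from the
  first-passage quadrature r₀⁻¹ = ∫ dc₁ e^(−h) ∫ dc₂ e^(h)/D, made
  self-consistent with the store balance
  r₀ = (1−⟨c_er*⟩)/(ε̂·τ_er·⟨c_er*⟩), ε̂ = ε/(1−ε/2); interval variance;
  the linearized store-relaxation timescale τ_theo; and predictors for
  the first interval T₀, the stationary interval T∞, the cumulative
  refractory period ΔT = T∞−T₀ and the transient length n_tr ≈ τ_theo/T₀;
* **spike statistics**: serial correlation coefficients ρ_k, their
  geometric-decay count n_corr, spike-train power spectra with the
  low-frequency identity S(f→0) = r₀·CV²·(1+2Σρ_k), transient fits of
  T_i = T∞ − (T∞−T₀)e^(−i/n_tr), and ensemble relaxation measures;
* a **two-step fitting pipeline** that extracts (T₀, n_tr, T∞, CV) from
  one ISI sequence and inverts the model for (τ, p, τ_er, ε);
* a **fixture generator** producing HEK-cell-like synthetic ISI
  sequences (exponential transient of the mean, inverse-Gaussian
  stationary intervals) for end-to-end validation.

## Worked example

```python
import caspike as cs

params = cs.ModelParams()            # tau=5 s, p=0.015, tau_er=300 s, eps=0.03
stats  = cs.cluster_stats(params.cluster)

theory = cs.self_consistent_state(params, stats)
print(f"r0* = {theory.r0_star:.5f} 1/s, <cer*> = {theory.cer_star:.3f}, "
      f"<T> = {theory.isi_mean:.1f} s, tau_theo = {theory.tau_theo:.1f} s")

trains = cs.simulate_langevin(params, t_end=2500.0, seed=42, n_trials=120,
                              stats=stats)
import numpy as np
isis = np.concatenate([np.diff(tr.spike_times)[8:] for tr in trains])
rho  = cs.serial_correlation(isis, k_max=3)
print(f"simulated <T> = {isis.mean():.1f} s, CV = {isis.std()/isis.mean():.2f}, "
      f"rho_1 = {rho[1]:.2f}")
```

prints

```
r0* = 0.00941 1/s, <cer*> = 0.921, <T> = 106.2 s, tau_theo = 81.8 s
simulated <T> = 102.5 s, CV = 0.35, rho_1 = -0.27
```

i.e. the store settles at ~92% filling, the theory predicts the
simulated stationary mean interval within a few percent, and adjacent
intervals are anticorrelated (ρ₁ ≈ −0.27, within the admissible band
(−1/2, 0) for monotonically decaying correlations).

A command-line interface mirrors the library:

```
caspike simulate --model langevin --trials 10 --t-end 2000 --seed 1 --out runs/
caspike theory
caspike stats --isi runs/isi_file.txt
caspike fit --isi cell1.txt --isi cell2.txt --out fits/ --seed 1
caspike buffer-scan --bt-grid 0,1,10,100 --out scan.json
```

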