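# tcsleep

A neural mass model of the sleeping thalamocortical loop, for computational
neuroscientists studying how the two hallmark rhythms of NREM sleep interact:
cortical **slow oscillations** (~1 Hz alternations of active UP and silent
DOWN states) and thalamic **sleep spindles** (waxing–waning 12–15 Hz bursts).
The package couples two established mass-modelling traditions into one hybrid
simulator and ships the complete analysis stack needed to quantify their
cross-frequency coupling.

## The model

**Thalamus.** Two populations — excitatory thalamocortical relay (TCR) and
inhibitory reticular (TRN) — with conductance-based membrane dynamics

τ V̇ = −(V − E_L) − w_e s_e (V − E_e) − w_i s_i (V − E_i) − (τ/C_m) I_int,

a sigmoidal rate function r(V) = r_max / (1 + exp(−C1 (V − θ)/σ)), and
second-order alpha-kernel synapses s̈ = γ²(input − s) − 2γṡ.  The intrinsic
currents are a potassium leak I_LK = g_LK (V − E_K), a low-threshold T-type
calcium current I_T = g_T m∞² h (V − E_Ca) (rebound bursting), and, in the
TCR, a calcium-modulated hyperpolarization-activated current
I_h = g_h (m_h1 + g_inc m_h2)(V − E_h) whose calcium-dependent upregulation
terminates each spindle — producing the waxing–waning envelope.

**Cortex.** A mean-field reduction of coupled populations of adaptive
exponential integrate-and-fire (AdEx) neurons: the mean membrane current
μ_α, the means and variances of the active-synapse fractions s̄_αβ, and the
mean spike-frequency adaptation current Ī_A evolve dynamically, while the
population rate, mean voltage and effective timescale come from precomputed
transfer functions r = Φ_r(μ, σ), V̄ = Φ_V(μ, σ), τ = Φ_τ(μ, σ), obtained by
steady-state Fokker–Planck threshold integration (with the adaptation shift
μ_E → μ_E − Ī_A/C).  Depending on the background currents the node is in a
DOWN or UP fixed point, a fast E–I limit cycle (~25 Hz), or an
adaptation-driven slow-oscillation limit cycle (≤ 2 Hz).

**Loop.** The cortical excitatory rate drives both thalamic populations
(strength N_ctx→thal) and the TCR rate drives the cortical excitatory
population (N_thal→ctx), each with a 13 ms conduction delay.  Background
drive is Ornstein–Uhlenbeck noise; everything is integrated with forward
Euler at dt = 0.01 ms and analysed at 100 Hz.

**Analysis stack.** An A7-style spindle detector (relative sigma power,
moving correlation, moving RMS), DOWN-state detection and event-locked
statistics, and cross-frequency coupling measures — Kullback–Leibler
modulation index (KL-MI), mean vector length (MVL), phase-locking value
(PLV) and phase–phase mutual information with equal-occupancy binning — with
significance from IAAFT surrogates (amplitude distribution preserved
exactly, power spectrum approximately).

## Worked example

```python
import numpy as np
from tcsleep import (ThalamicParams, SimGrid, simulate_thalamus,
                     detect_spindles, spindle_density)

params = ThalamicParams()          # spindling regime defaults
grid = SimGrid(duration=65000.0)   # 65 s, dt = 0.01 ms, output at 100 Hz
out = simulate_thalamus(params, grid)
post = out["t"] > 5000.0           # discard the 5 s transient
events = detect_spindles(out["r_TCR"][post], fs=grid.fs)
dens = spindle_density(events, post.sum() / grid.fs)
print(f"{len(events)} spindles in {post.sum() / grid.fs:.0f} s "
      f"({dens['per_minute']:.1f} per minute)")
print(f"mean duration  : {np.mean([e.duration for e in events]):.2f} s")
print(f"mean frequency : {np.mean([e.mean_frequency for e in events]):.1f} Hz")
```

prints

```
11 spindles in 60 s (11.0 per minute)
mean duration  : 0.62 s
mean frequency : 13.5 Hz
```

— spontaneous waxing–waning spindles at a ~13 Hz carrier, 0.5–1 s long, at a
density just above the 2–10 per minute reported for human EEG (noise-free
spindling is more regular than the real thing).  The same API runs
the isolated cortex (`simulate_cortex`) and the full loop (`simulate_loop`),
and `tcsleep.cfc.surrogate_test_multi` quantifies slow-oscillation/spindle
coupling with an IAAFT null.

A CLI mirrors the library for shell use:

```bash
tcsleep simulate --node loop --duration 30000 --seed 1 --out runs/
tcsleep detect --in runs/loop_rates.csv --column r_TCR --out spindles.tsv
tcsleep cfc --in runs/loop_rates.csv --stats klmi,mvl,plv,mi --n-surr 1000 \
        --seed 1 --out cfc.json
tcsleep sweep-thalamus --g-lk 0.01 0.05 9 --g-h 0.02 0.08 9 --out map.csv
```

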