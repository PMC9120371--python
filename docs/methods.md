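# Methods

This note documents the scientific and numerical choices behind `tcsleep`:
what each model component assumes, where its parameters come from, how the
analyses are defined, and what the package does and does not claim.

## Thalamic node

The thalamus is a two-population mass model: thalamocortical relay (TCR,
excitatory) and reticular (TRN, inhibitory).  Mean membrane potentials obey
a conductance-based equation with membrane time constant τ = 20 ms and
capacitance C_m = 1 µF/cm²; rates follow a sigmoid with r_max = 400 Hz,
θ = −58.5 mV, gain σ = 6 mV and slope prefactor C1 = π/√3.  The prefactor is
part of the source conductance-based mass-model family; we verified
numerically that only the C1 variant reproduces the model's known corner
fixed points (the up-state corner at 116 Hz is matched to three significant
figures; the down-state corner settles at 8.93 Hz against a nominal 10 Hz —
the one residual quantitative discrepancy we know of, see *Limitations*).

Intrinsic currents (all kinetics in `thalamus/kinetics.py`, with the
literature lineage noted there):

* **I_LK** — potassium leak, g_LK (V − E_K); its conductance sets the tonic
  hyperpolarization level and is one axis of the spindling phase diagram.
* **I_T** — low-threshold calcium current g_T m∞²(V) h (V − E_Ca) with
  instantaneous activation and dynamic inactivation h; TCR and TRN use their
  respective published kinetic variants, with Q10-corrected (36 °C) time
  constants.  De-inactivation under hyperpolarization enables the rebound
  bursts that make spindle oscillations possible.
* **I_h** (TCR only) — hyperpolarization-activated cation current with a
  two-state open mechanism: a fraction m_h1 of channels opens with voltage,
  and calcium binding (instantaneous binding probability
  P(Ca) = k1 Ca⁴/(k1 Ca⁴ + k2)) locks channels into a bound open state m_h2
  with conductance scaling g_inc = 2.  Calcium enters through I_T
  (dCa/dt = α_Ca I_T − (Ca − Ca_0)/τ_Ca).  Spindle termination works through
  this loop: bursts → calcium → upregulated I_h → TCR depolarization → no
  further rebound, which yields the waxing–waning envelope.

Synapses are conductance-based with alpha-function response kernels
γ² t e^(−γt) (γ_AMPA = 70 s⁻¹, γ_GABA = 100 s⁻¹), realized as the critically
damped second-order ODE; a unit test checks the ODE against direct
convolution.  Connectivity: TRN→TCR 5, TCR→TRN 3, TRN→TRN 25 (TCR makes no
local recurrent connections).  Background noise is an Ornstein–Uhlenbeck
process (zero drift, τ = 5 ms) on the TCR's excitatory synaptic input.

Defaults put the node in spindling "region I" (g_LK = 0.018,
g_h = 0.062 mS/cm²): spontaneous, noise-free waxing–waning spindles at a
~13 Hz carrier.  A second spindling region exists near g_LK ≈ 0.030; between
and around them the node shows continuous sigma-band oscillation (no
envelope) or fixed points.  The TCR's g_T tunes the carrier across the
12–15 Hz fast-spindle band; the TRN's g_T has little effect.

## Cortical node

The cortex is a mean-field model of delay-coupled excitatory (E, with
somatic spike-frequency adaptation) and inhibitory (I) AdEx populations in
the linear–nonlinear cascade formulation: dynamic state = mean membrane
currents μ_E, μ_I (relaxing with the state-dependent timescale Φ_τ), mean
adaptation current Ī_A, and mean/variance of the active-synapse fractions
per connection; outputs = rate and mean voltage through the precomputed
transfer maps Φ_r, Φ_V.

**Transfer tables.** Φ_r and Φ_V come from steady-state threshold
integration of the Fokker–Planck equation for an exponential
integrate-and-fire neuron under white-noise input (backward integration of
the stationary density from the spike threshold with reinjection at the
reset and a refractory correction; overflow-guarded for small σ).  Φ_τ is
obtained from the linear rate response r₁(ω) (computed with the same
machinery) by least-squares fitting the low-pass model r₁(0)/(1 + iωτ) over
1–60 Hz.  The default grid is 400 μ-points × 40 σ-points over
[−3, 7] mV/ms × [0.25, 5] mV/√ms, bilinearly interpolated and clamped at the
boundary.  Validation: table rates and voltages agree with a brute-force
Monte-Carlo population of 2000 AdEx neurons to <1% (tested at 5%), the
ω→0 response equals the finite-difference rate slope, and the fitted τ is
consistent with Monte-Carlo step-response rise times (the exponential
approximation cannot represent the spike-frequency ringing of strongly
mean-driven states; this is inherent to the cascade reduction).

**Parameters.** Single-neuron and connectivity constants are the source
mean-field cortical model's published set (C = 200 pF, g_L = 10 nS,
E_L = −65 mV, Δ_T = 1.5 mV, V_T = −50 mV, V_s = −40 mV, V_r = −70 mV,
T_ref = 1.5 ms; J_EE = 2.43, J_EI = −3.3, J_IE = 2.6, J_II = −1.64 mV/ms;
c_EE = c_IE = 0.3, c_EI = c_II = 0.5; K_E = 800, K_I = 200; τ_se = 2 ms,
τ_si = 5 ms; internal delays 4 ms on excitatory and 2 ms on inhibitory
rates; σ_ext = 1.5 mV/√ms).  The adaptation triple is not uniquely published
for the sleep regime; it was calibrated once against the printed regime
anchors — slow limit cycle (≤ 2 Hz) at μ_E = 0.56 nA, μ_I = 0.4 nA; UP fixed
point with noise-driven DOWN excursions at μ_E = 0.61 nA; fast E–I cycle
near 25 Hz at weak inhibition — giving a = 0 nS, b = 30 pA, τ_A = 600 ms.
Background currents are quoted in nA (1 mV/ms ≡ 0.2 nA at C = 200 pF).

**Regimes.** Increasing μ_E at μ_I = 0.4 nA crosses DOWN fixed point →
slow adaptation-driven limit cycle → UP fixed point; at weak μ_I a fast
E–I limit cycle (~25 Hz; reference coordinate (0.35, 0.1) nA) replaces the
slow one.  In this reconstruction the oscillatory wedge's left border sits
at μ_E ≈ 0.53 nA and the wedge closes below μ_I ≈ 0.7 nA — slightly
narrower than the source model's published diagrams; regime topology and
the anchor coordinates above are reproduced.

## The loop

Cortical r_E enters both thalamic AMPA inputs as
N_ctx→thal · r_E(t − 13 ms); TCR rate enters the cortical E population's
effective input rate as N_thal→ctx · r_TCR(t − 13 ms) (through the same
c_EE K_E scaling as local input).  Rates cross the interface in kHz
(internal ms-based units); both coupling strengths are free parameters, with
roughly a tenfold asymmetry expected from the nodes' maximum rates.  With
both couplings zero, the loop reproduces each isolated node bit-exactly
(per-source RNG streams are spawned from one master seed).  The reference
coupled experiment (120 s; μ_E = 0.61 nA, μ_I = 0.4 nA,
σ_E = σ_I = 0.05 mV/ms^{3/2}, σ_TCR = 0.005 mV/ms^{3/2}, N_thal→ctx = 0.12,
N_ctx→thal = 1.2, thalamic g_LK = 0.033 mS/cm²) produces an UP-dominant
cortex with irregular DOWN states; DOWN windows release the TCR from
depolarizing drive, enabling rebound spindles that feed back into the
following UP state.

## Numerics

Forward Euler at dt = 0.01 ms (trajectory changes < 1% RMS under dt
halving); OU noise pre-integrated on the dt grid (Euler–Maruyama) and
inserted with zero-order hold; delays as ring buffers of exactly
round(d/dt) steps, pre-filled with the initial state so fixed points stay
fixed; outputs subsampled at dt_samp = 10 ms (100 Hz analysis rate); the
first 5 s of every statistic-producing run are discarded; cortical synaptic
means are clamped to [0, 1] and variances to ≥ 0 after each step;
divergence (non-finite state) raises with the failure time.

## Spindle detection

A7-style, on z-scored signals at 100 Hz: (1) relative sigma power
(12–15 Hz over 1–30 Hz) from a sliding 2 s spectrogram; (2) moving Pearson
correlation (0.3 s windows, 0.1 s steps) between the broadband and
sigma-filtered signal; (3) moving RMS of the sigma-filtered signal,
thresholded at mean + 1.5 SD.  All three streams must agree (conjunctive
rule); supra-threshold segments closer than 0.5 s are merged, refined to the
sigma envelope's half-peak extent (the decision streams are window-smeared;
the envelope localizes the burst), and filtered to durations within
[0.5, 2.5] s.  For cortical rates the minimum duration drops to 0.3 s and
the relative-power threshold from 0.2 to 0.15 (cortical spindle imprints are
briefer and ride on broadband slow activity).  The conjunctive rule is what
makes the detector specific on noise and able to reject the
continuous-oscillation regime (whose segments exceed the maximum duration);
a disjunctive 2-of-3 rule fails both.  Mean event frequency is counted
between the first and last zero crossing of the sigma-filtered segment.

DOWN states: the excitatory rate is smoothed with a 100 ms moving average
(removing the spindle ripple), then intervals below
p5 + 0.25 (p95 − p5) lasting ≥ 100 ms are DOWN states (scale-free across
parametrizations); a DOWN state is "spindle-followed" if a spindle peak
occurs within 1.5 s after its midpoint.

## Cross-frequency coupling

Signals are band-passed with a one-pass zero-phase FIR filter (SO band
0.1–3 Hz, fast-spindle band 12–15 Hz), then Hilbert-transformed for
instantaneous phase and amplitude.  Statistics:

* **KL-MI** — amplitudes binned by SO phase (18 bins by default),
  normalized to a distribution P; KL-MI = (log N − H(P))/log N ∈ [0, 1].
* **MVL** — mean over time of A(t) e^{iφ(t)}; magnitude = coupling strength,
  argument = preferred SO phase.  Implemented as a time-average (so values
  are length-independent); published sums differ by the sample count.
* **PLV** — |mean e^{i(φ_SO − φ_spindle)}| ∈ [0, 1] (also a time-average).
* **MI** — mutual information (nats) between the two phase series with
  16 equal-occupancy bins per margin.

Significance: 1000 IAAFT surrogates of the raw spindle-carrying signal
(iterative spectrum/rank adjustment; the amplitude distribution is exact by
construction, the spectrum converges to <1% relative error; stopping at
200 iterations or when the spectrum mismatch stops improving).  The SO
phase series stays fixed; phase/amplitude are re-extracted per surrogate and
the statistic recomputed, giving the one-sided empirical p-value
(1 + #{null ≥ observed})/(1 + n).  All four statistics can share one
surrogate set.

## Synthetic fixtures

The PAC fixture superposes a slow cosine and a fast carrier whose envelope
is 1 + m cos(φ_slow − φ0), plus white noise; m and φ0 are exact ground
truth.  The slow phase wanders as a random walk (0.4 rad/√s by default),
mimicking the irregular, noise-timed slow oscillation of the model.  This
wander matters for significance testing: for a strictly periodic fixture,
spectrum-preserving surrogates retain a periodically modulated envelope and
KL-MI is invariant to the phase offset, so no surrogate test can reject —
an instructive property, not a bug, and the reason the default is
aperiodic.  The spindle-train fixture places non-overlapping
Gaussian-envelope sigma bursts (FWHM = nominal duration) on a noise floor
with stored onset/offset/peak ground truth.  What passing fixture tests do
not show: real EEG morphology, artifacts, or 1/f backgrounds — the detector
and CFC settings here are tuned for model rates, not empirical recordings.

## Problem sizes

Statistic-producing runs use 20 s (fixed points), 40–65 s (spindle counts,
frequency sweeps) and 120 s (loop CFC) of simulated time; sweeps in the
test-suite run on coarse grids (≤ 15×15), with full grids available through
the CLI.  The acceptance script reruns everything from scratch in a few
minutes on one core.

## Known limitations

* The thalamic down-state corner settles at 8.93 Hz (nominal 10 Hz); the
  up-state corner matches exactly.  We attribute the gap to an unresolved
  minor kinetic constant of the source model's supplementary material.
* The adaptation calibration caps the UP-state rate near 14 Hz at the
  reference coupled operating point (the source model reports 50–60 Hz UP
  rates).  Consequently corticothalamic spindle suppression during UP states
  is weaker, the SO-phase modulation of spindle amplitude is roughly 5×
  shallower than the source study's (KL-MI ~0.001–0.002 vs ~0.011), its
  significance reaches p ≈ 0.01 rather than p ≤ 0.001, and the preferred
  coupling phase sits just before the SO peak (−0.6…−0.2 rad) rather than
  just after ([0, π/4]).  The qualitative dissociation — phase-amplitude
  coupling significant, phase-phase coupling absent — reproduces robustly.
* Φ_τ is a single-exponential approximation of the population's linear
  response; resonant ringing near the firing rate is not represented.
* The slow-oscillation wedge of the cortical state space is somewhat
  narrower than in the source model's published diagrams (left border
  ~0.53 nA instead of ~0.47 nA at μ_I = 0.4 nA).
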