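"""Brute-force Monte-Carlo simulation of an uncoupled AdEx population.

Independent oracle for the precomputed transfer functions: a population of
exponential integrate-and-fire neurons (adaptation switched off) driven by
white noise with mean ``mu`` and standard deviation ``sigma`` should fire,
in the stationary state, at the rate the threshold-integration table
predicts.  Deliberately simple Euler-Maruyama machinery, kept free of the
Fokker-Planck code path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .transfer import AdExNeuronParams

__all__ = ["mc_population_rate"]


@njit(cache=True)
def _mc_run(n_neurons, n_steps, dt, mu, sigma, EL, DeltaT, VT, Vr, Vs,
            tau_m, Tref, t_warm, seed):
    np.random.seed(seed)
    V = np.full(n_neurons, EL)
    refrac = np.zeros(n_neurons)
    n_spikes = 0
    vsum = 0.0
    n_v = 0
    sq = sigma * np.sqrt(dt)
    for i in range(n_steps):
        t = i * dt
        counting = t >= t_warm
        for j in range(n_neurons):
            if refrac[j] > 0.0:
                refrac[j] -= dt
                V[j] = Vr
            else:
                v = V[j]
                f = ((EL - v) + DeltaT * np.exp((v - VT) / DeltaT)) / tau_m
                v += dt * (f + mu) + sq * np.random.normal()
                if v >= Vs:
                    v = Vr
                    refrac[j] = Tref
                    if counting:
                        n_spikes += 1
                V[j] = v
            if counting:
                vsum += V[j]
                n_v += 1
    return n_spikes, vsum / max(n_v, 1)


def mc_population_rate(
    neuron: AdExNeuronParams,
    mu: float,
    sigma: float,
    n_neurons: int = 2000,
    duration: float = 2000.0,
    warmup: float = 500.0,
    dt: float = 0.02,
    seed: int = 0,
) -> tuple[float, float]:
    """Stationary (rate in Hz, mean voltage in mV) of the spiking population."""
    n_steps = int(round((duration + warmup) / dt))
    n_spikes, vbar = _mc_run(
        n_neurons, n_steps, dt, mu, sigma, neuron.E_L, neuron.Delta_T,
        neuron.V_T, neuron.V_r, neuron.V_s, neuron.tau_m, neuron.T_ref,
        warmup, seed)
    rate_hz = n_spikes / (n_neurons * duration * 1e-3)
    return rate_hz, vbar
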