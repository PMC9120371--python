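"""Conductance-based two-population thalamic mass model.

An excitatory thalamocortical relay population (TCR) and an inhibitory
reticular population (TRN) interact through conductance-based synapses with
alpha-function response kernels.  Intrinsic T-type calcium currents support
rebound bursting and the calcium-modulated I_h current of the TCR produces
the waxing-waning envelope of sleep spindles (12-15 Hz).

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.  Firing rates are carried
internally in 1/ms; all public outputs are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from ..numerics import OUParams, SimGrid, spawn_streams
from . import kinetics as K

__all__ = ["ThalamicParams", "firing_rate", "intrinsic_currents",
           "steady_init", "simulate_thalamus"]


@dataclass(frozen=True)
class ThalamicParams:
    """Thalamic node parameters (defaults: spindling region I).

    Defaults follow the published parameter set of the source
    conductance-based thalamic mass model (Schellenberger Costa et al. 2016).
    """

    tau_t: float = 20.0      # TCR membrane time constant (ms)
    tau_r: float = 20.0      # TRN membrane time constant (ms)
    C_m: float = 1.0         # membrane capacitance (uF/cm^2)
    E_L: float = -70.0       # leak reversal (mV)
    E_e: float = 0.0         # AMPA reversal (mV)
    E_i: float = -70.0       # GABA_A reversal (mV)
    E_K: float = -100.0      # potassium reversal (mV)
    E_Ca: float = 120.0      # calcium reversal (mV)
    E_h: float = -40.0       # I_h reversal (mV)
    r_max: float = 400.0     # maximum firing rate (Hz)
    theta: float = -58.5     # sigmoid threshold (mV)
    sigma_gain: float = 6.0  # sigmoid gain (mV)
    c1: float = float(np.pi / np.sqrt(3.0))  # sigmoid slope prefactor
    g_LK: float = 0.018      # potassium leak conductance, both populations
    g_T_t: float = 3.0       # TCR T-current conductance
    g_T_r: float = 2.3       # TRN T-current conductance
    g_h: float = 0.062       # TCR I_h conductance
    g_inc: float = 2.0       # conductivity scaling of Ca-bound I_h state
    alpha_Ca: float = -51.8e-6  # Ca influx per unit I_T (mM cm^2 / (uA ms))
    tau_Ca: float = 10.0     # Ca decay time (ms)
    Ca_0: float = 2.4e-4     # resting Ca concentration (mM)
    k1: float = 2.5e7        # Ca binding rate (mM^-4 ms^-1)
    k2: float = 4.0e-4       # unbinding rate (ms^-1)
    k3: float = 0.1          # I_h state binding rate (ms^-1)
    k4: float = 1.0e-3       # I_h state unbinding rate (ms^-1)
    n_P: float = 4.0         # Ca binding cooperativity
    gamma_e: float = 0.07    # AMPA response decay (ms^-1)
    gamma_i: float = 0.1     # GABA_A response decay (ms^-1)
    w_e: float = 1.0         # excitatory synaptic scaling (ms)
    w_i: float = 1.0         # inhibitory synaptic scaling (ms)
    N_tr: float = 5.0        # TRN -> TCR strength
    N_rt: float = 3.0        # TCR -> TRN strength
    N_rr: float = 25.0       # TRN -> TRN strength

    def __post_init__(self):
        for name in ("g_LK", "g_T_t", "g_T_r", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_max <= 0 or self.sigma_gain <= 0:
            raise ValueError("r_max and sigma_gain must be > 0")
        if self.gamma_e <= 0 or self.gamma_i <= 0:
            raise ValueError("synaptic decay constants must be > 0")

    def with_(self, **kw) -> "ThalamicParams":
        return replace(self, **kw)

    def to_array(self) -> np.ndarray:
        return np.array([
            self.tau_t, self.tau_r, self.C_m, self.E_L, self.E_e, self.E_i,
            self.E_K, self.E_Ca, self.E_h,
            self.r_max * 1e-3, self.theta, self.sigma_gain, self.c1,
            self.g_LK, self.g_T_t, self.g_T_r, self.g_h, self.g_inc,
            self.alpha_Ca, self.tau_Ca, self.Ca_0,
            self.k1, self.k2, self.k3, self.k4, self.n_P,
            self.gamma_e, self.gamma_i, self.w_e, self.w_i,
            self.N_tr, self.N_rt, self.N_rr,
        ])


# parameter array indices (keep in sync with ThalamicParams.to_array)
(_TAU_T, _TAU_R, _CM, _EL, _EE, _EI, _EK, _ECA, _EH,
 _RMAX, _THETA, _SIG, _C1,
 _GLK, _GTT, _GTR, _GH, _GINC,
 _ACA, _TCA, _CA0, _K1, _K2, _K3, _K4, _NP,
 _GE, _GI, _WE, _WI, _NTR, _NRT, _NRR) = range(33)

#: state vector layout
STATE_NAMES = ("V_t", "V_r", "h_T_t", "h_T_r", "m_h1", "m_h2", "Ca",
               "s_et", "ds_et", "s_it", "ds_it",
               "s_er", "ds_er", "s_ir", "ds_ir")
N_STATE = len(STATE_NAMES)


def firing_rate(V, params: ThalamicParams):
    """Population firing rate in Hz for membrane potential V (mV)."""
    V = np.asarray(V, dtype=float)
    return params.r_max / (1.0 + np.exp(
        -params.c1 * (V - params.theta) / params.sigma_gain))


def intrinsic_currents(state: np.ndarray, params: ThalamicParams,
                       population: str) -> dict[str, float]:
    """Intrinsic currents (uA/cm^2) at the given state, per population."""
    p = params
    if population == "TCR":
        V, h = state[0], state[2]
        I_T = p.g_T_t * K.m_inf_T_t(V) ** 2 * h * (V - p.E_Ca)
        I_h = p.g_h * (state[4] + p.g_inc * state[5]) * (V - p.E_h)
        return {"I_LK": p.g_LK * (V - p.E_K), "I_T": I_T, "I_h": I_h}
    if population == "TRN":
        V, h = state[1], state[3]
        I_T = p.g_T_r * K.m_inf_T_r(V) ** 2 * h * (V - p.E_Ca)
        return {"I_LK": p.g_LK * (V - p.E_K), "I_T": I_T}
    raise ValueError(f"unknown population {population!r}")


def steady_init(params: ThalamicParams) -> np.ndarray:
    """Initial state: V at E_L, gates at steady state for that V, synapses 0."""
    V = params.E_L
    y = np.zeros(N_STATE)
    y[0] = y[1] = V
    y[2] = K.h_inf_T_t(V)
    y[3] = K.h_inf_T_r(V)
    minf = K.m_inf_h(V)
    y[4] = minf / (1.0 + minf)
    P = K.ca_binding(params.Ca_0, params.k1, params.k2, params.n_P)
    y[5] = params.k3 * P / params.k4 * y[4]
    y[6] = params.Ca_0
    return y


@njit(cache=True)
def thal_deriv(y, P, ext_e, noise, dy):
    """Thalamic state derivative; ext_e and noise are rate inputs in 1/ms."""
    V_t, V_r = y[0], y[1]
    h_t, h_r, m1, m2, Ca = y[2], y[3], y[4], y[5], y[6]

    r_t = K.firing_rate(V_t, P[_RMAX], P[_THETA], P[_SIG] / P[_C1])
    r_r = K.firing_rate(V_r, P[_RMAX], P[_THETA], P[_SIG] / P[_C1])

    # intrinsic currents
    I_LK_t = P[_GLK] * (V_t - P[_EK])
    mT = K.m_inf_T_t(V_t)
    I_T_t = P[_GTT] * mT * mT * h_t * (V_t - P[_ECA])
    I_h = P[_GH] * (m1 + P[_GINC] * m2) * (V_t - P[_EH])

    I_LK_r = P[_GLK] * (V_r - P[_EK])
    mR = K.m_inf_T_r(V_r)
    I_T_r = P[_GTR] * mR * mR * h_r * (V_r - P[_ECA])

    # membrane potentials
    dy[0] = (-(V_t - P[_EL])
             - P[_WE] * y[7] * (V_t - P[_EE])
             - P[_WI] * y[9] * (V_t - P[_EI])) / P[_TAU_T] \
        - (I_LK_t + I_T_t + I_h) / P[_CM]
    dy[1] = (-(V_r - P[_EL])
             - P[_WE] * y[11] * (V_r - P[_EE])
             - P[_WI] * y[13] * (V_r - P[_EI])) / P[_TAU_R] \
        - (I_LK_r + I_T_r) / P[_CM]

    # T-current inactivation gates
    dy[2] = (K.h_inf_T_t(V_t) - h_t) / K.tau_h_T_t(V_t)
    dy[3] = (K.h_inf_T_r(V_r) - h_r) / K.tau_h_T_r(V_r)

    # I_h two-state gating with instantaneous calcium binding
    Pb = K.ca_binding(Ca, P[_K1], P[_K2], P[_NP])
    minf = K.m_inf_h(V_t)
    dy[4] = (minf * (1.0 - m1) - m1) / K.tau_m_h(V_t) \
        - P[_K3] * Pb * m1 + P[_K4] * m2
    dy[5] = P[_K3] * Pb * m1 - P[_K4] * m2

    # calcium pool fed by the T-current
    dy[6] = P[_ACA] * I_T_t - (Ca - P[_CA0]) / P[_TCA]

    # second-order alpha-kernel synapses; noise rides on the TCR AMPA input
    ge2 = P[_GE] * P[_GE]
    gi2 = P[_GI] * P[_GI]
    dy[7] = y[8]
    dy[8] = ge2 * (ext_e + noise - y[7]) - 2.0 * P[_GE] * y[8]
    dy[9] = y[10]
    dy[10] = gi2 * (P[_NTR] * r_r - y[9]) - 2.0 * P[_GI] * y[10]
    dy[11] = y[12]
    dy[12] = ge2 * (P[_NRT] * r_t + ext_e - y[11]) - 2.0 * P[_GE] * y[12]
    dy[13] = y[14]
    dy[14] = gi2 * (P[_NRR] * r_r - y[13]) - 2.0 * P[_GI] * y[14]


@njit(cache=True)
def _run(y0, P, dt, n_steps, dec, ext_e, noise, V_out):
    y = y0.copy()
    dy = np.empty(N_STATE)
    n_out = n_steps // dec
    for i in range(n_steps):
        thal_deriv(y, P, ext_e[i], noise[i], dy)
        for j in range(N_STATE):
            y[j] += dt * dy[j]
        if (i + 1) % dec == 0:
            k = (i + 1) // dec - 1
            if k < n_out:
                V_out[0, k] = y[0]
                V_out[1, k] = y[1]
            if not (np.isfinite(y[0]) and np.isfinite(y[1])):
                return (i + 1) * dt
    return -1.0


def simulate_thalamus(
    params: ThalamicParams,
    grid: SimGrid,
    ou: OUParams | None = None,
    external_rate: np.ndarray | None = None,
    coupling: float = 1.0,
    initial_state: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate the isolated thalamic node.

    Parameters
    ----------
    ou : OUParams, optional
        Background noise on the TCR excitatory synaptic input (sigma in the
        model's rate units per sqrt(ms)).  ``None`` means noise-free.
    external_rate : array, optional
        External excitatory drive in Hz, entering the AMPA inputs of both
        populations scaled by ``coupling``.  Either one value per integration
        step or one per output sample (zero-order held).
    rng : numpy Generator, optional
        Noise stream; by default one is spawned from ``grid.seed`` (stream
        "TCR" of the master seed).

    Returns
    -------
    dict with keys ``t`` (ms), ``r_TCR``, ``r_TRN`` (Hz), ``V_t``, ``V_r``
    (mV), each at ``dt_samp`` resolution.
    """
    from ..numerics import ou_process

    P = params.to_array()
    n = grid.n_steps
    if ou is None or ou.sigma == 0.0:
        noise = np.zeros(n)
        if ou is not None and ou.mu != 0.0:
            noise.fill(ou.mu)
    else:
        if rng is None:
            rng = spawn_streams(grid.seed, ("TCR", "E", "I"))["TCR"]
        noise = ou_process(ou, grid, rng)

    if external_rate is None:
        ext = np.zeros(n)
    else:
        ext = np.asarray(external_rate, dtype=float) * 1e-3 * coupling  # Hz -> 1/ms
        if ext.size != n:
            ext = np.repeat(ext, max(1, n // ext.size))[:n]
        if ext.size < n:
            ext = np.pad(ext, (0, n - ext.size), mode="edge")

    y0 = steady_init(params) if initial_state is None else initial_state
    n_out = n // grid.decimation
    V_out = np.empty((2, n_out))
    t_fail = _run(y0, P, grid.dt, n, grid.decimation, ext, noise, V_out)
    if t_fail >= 0:
        raise FloatingPointError(
            f"thalamic state diverged at t = {t_fail:.2f} ms")
    t = grid.times()
    return {
        "t": t,
        "V_t": V_out[0],
        "V_r": V_out[1],
        "r_TCR": firing_rate(V_out[0], params),
        "r_TRN": firing_rate(V_out[1], params),
    }
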