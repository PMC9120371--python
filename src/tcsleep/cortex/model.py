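"""Mean-field cortical node: delay-coupled E-I populations of AdEx neurons.

The state of each population is its mean membrane current (mV/ms, reported
to users in nA after multiplication by the membrane capacitance), the means
and variances of the fractions of active synapses per connection, and (for
the excitatory population) the mean somatic adaptation current.  Population
rates, mean voltages and the effective input timescale come from the
precomputed transfer table (see :mod:`.transfer`).

Depending on the background currents to E and I the node sits in a DOWN or
UP fixed point, a fast E-I limit cycle (~25 Hz) or an adaptation-driven
slow-oscillation limit cycle (<~2 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from ..numerics import OUParams, SimGrid, ou_process, spawn_streams, delay_steps
from .transfer import AdExNeuronParams, TransferTable, build_transfer_table, \
    _interp2_scalar

__all__ = ["CorticalParams", "simulate_cortex", "NA_PER_MVMS"]

#: 1 mV/ms of mean membrane current equals 0.2 nA at C_m = 200 pF
NA_PER_MVMS = 0.2


@dataclass(frozen=True)
class CorticalParams:
    """Cortical node parameters (defaults: source model's published set)."""

    # coupling strengths J_ab (mV/ms), a = target, b = source
    J_EE: float = 2.43
    J_EI: float = -3.30
    J_IE: float = 2.60
    J_II: float = -1.64
    # synaptic increment constants c_ab and in-degrees K_b
    c_EE: float = 0.3
    c_EI: float = 0.5
    c_IE: float = 0.3
    c_II: float = 0.5
    K_E: float = 800.0
    K_I: float = 200.0
    tau_se: float = 2.0      # excitatory synaptic time constant (ms)
    tau_si: float = 5.0      # inhibitory synaptic time constant (ms)
    d_E: float = 4.0         # delay on excitatory rates (ms)
    d_I: float = 2.0         # delay on inhibitory rates (ms)
    # background drive (OU): drifts in nA, sigma in mV/ms^{3/2}
    mu_E_drift: float = 0.4
    mu_I_drift: float = 0.3
    sigma_E: float = 0.0
    sigma_I: float = 0.0
    tau_ou: float = 5.0
    # constant external contribution to the current variance (mV/sqrt(ms))
    sigma_ext_E: float = 1.5
    sigma_ext_I: float = 1.5
    neuron: AdExNeuronParams = AdExNeuronParams()

    def __post_init__(self):
        if self.tau_se <= 0 or self.tau_si <= 0 or self.tau_ou <= 0:
            raise ValueError("time constants must be > 0")
        if self.K_E <= 0 or self.K_I <= 0:
            raise ValueError("in-degrees must be positive")

    def with_(self, **kw) -> "CorticalParams":
        return replace(self, **kw)

    @property
    def mu_E_mvms(self) -> float:
        return self.mu_E_drift / NA_PER_MVMS

    @property
    def mu_I_mvms(self) -> float:
        return self.mu_I_drift / NA_PER_MVMS


# cortical state layout
CTX_STATE = ("mu_f_E", "mu_f_I", "I_A",
             "s_EE", "s_EI", "s_IE", "s_II",
             "v_EE", "v_EI", "v_IE", "v_II")
N_CTX = len(CTX_STATE)


@njit(cache=True)
def ctx_deriv(y, P, z1ee, z1ei, z1ie, z1ii, z2ee, z2ei, z2ie, z2ii,
              mue_ext, mui_ext, mug, sgg, r_t, v_t, tau_t, dy):
    """Cortical state derivative given effective input rates z1/z2 (1/ms).

    Returns (r_E, r_I) in kHz.  P layout:
    [J_EE, J_EI, J_IE, J_II, tau_se, tau_si, sigma_ext_E, sigma_ext_I,
     a, E_A, tau_A, b, C_m, tau_m]
    """
    J_EE, J_EI, J_IE, J_II = P[0], P[1], P[2], P[3]
    tau_se, tau_si = P[4], P[5]
    sxE, sxI = P[6], P[7]
    a, E_A, tau_A, b, C = P[8], P[9], P[10], P[11], P[12]
    taum = P[13]

    seem, seim, siem, siim = y[3], y[4], y[5], y[6]
    seev, seiv, siev, siiv = y[7], y[8], y[9], y[10]

    # current variance (Eq of the mean-field reduction)
    sigE = np.sqrt(
        2.0 * J_EE * J_EE * seev * tau_se * taum / ((1.0 + z1ee) * taum + tau_se)
        + 2.0 * J_EI * J_EI * seiv * tau_si * taum / ((1.0 + z1ei) * taum + tau_si)
        + sxE * sxE)
    sigI = np.sqrt(
        2.0 * J_IE * J_IE * siev * tau_se * taum / ((1.0 + z1ie) * taum + tau_se)
        + 2.0 * J_II * J_II * siiv * tau_si * taum / ((1.0 + z1ii) * taum + tau_si)
        + sxI * sxI)

    mu_eff_E = y[0] - y[2] / C   # adaptation shifts all E lookups
    r_E = _interp2_scalar(mug, sgg, r_t, mu_eff_E, sigE) * 1e-3  # kHz
    V_E = _interp2_scalar(mug, sgg, v_t, mu_eff_E, sigE)
    tau_E = _interp2_scalar(mug, sgg, tau_t, mu_eff_E, sigE)
    r_I = _interp2_scalar(mug, sgg, r_t, y[1], sigI) * 1e-3
    tau_I = _interp2_scalar(mug, sgg, tau_t, y[1], sigI)
    if tau_E < 0.01:
        tau_E = 0.01
    if tau_I < 0.01:
        tau_I = 0.01

    dy[0] = (J_EE * seem + J_EI * seim + mue_ext - y[0]) / tau_E
    dy[1] = (J_IE * siem + J_II * siim + mui_ext - y[1]) / tau_I
    dy[2] = (a * (V_E - E_A) - y[2]) / tau_A + b * r_E

    dy[3] = -seem / tau_se + (1.0 - seem) * z1ee
    dy[4] = -seim / tau_si + (1.0 - seim) * z1ei
    dy[5] = -siem / tau_se + (1.0 - siem) * z1ie
    dy[6] = -siim / tau_si + (1.0 - siim) * z1ii

    dy[7] = (1.0 - seem) ** 2 * z2ee \
        + (z2ee - 2.0 * tau_se * (z2ee + 1.0)) * seev / tau_se ** 2
    dy[8] = (1.0 - seim) ** 2 * z2ei \
        + (z2ei - 2.0 * tau_si * (z2ei + 1.0)) * seiv / tau_si ** 2
    dy[9] = (1.0 - siem) ** 2 * z2ie \
        + (z2ie - 2.0 * tau_se * (z2ie + 1.0)) * siev / tau_se ** 2
    dy[10] = (1.0 - siim) ** 2 * z2ii \
        + (z2ii - 2.0 * tau_si * (z2ii + 1.0)) * siiv / tau_si ** 2
    return r_E, r_I


@njit(cache=True)
def _run_cortex(y0, P, cK, dt, n_steps, dec, n_de, n_di,
                mue_ext, mui_ext, ext_rate, mug, sgg, r_t, v_t, tau_t,
                out):
    """cK layout: [cEE*KE, cEI*KI, cIE*KE, cII*KI, cEE, cEI, cIE, cII]."""
    y = y0.copy()
    dy = np.empty(N_CTX)
    re_hist = np.empty(n_de)
    ri_hist = np.empty(n_di)
    # pre-fill rate histories with the initial-state rates
    r_E, r_I = ctx_deriv(y, P, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                         mue_ext[0], mui_ext[0], mug, sgg, r_t, v_t, tau_t, dy)
    for i in range(n_de):
        re_hist[i] = r_E
    for i in range(n_di):
        ri_hist[i] = r_I
    ie = 0
    ii = 0
    n_out = n_steps // dec
    for i in range(n_steps):
        rd_e = re_hist[ie]
        rd_i = ri_hist[ii]
        ext = ext_rate[i]
        z1ee = cK[0] * (rd_e + ext)
        z1ei = cK[1] * rd_i
        z1ie = cK[2] * rd_e
        z1ii = cK[3] * rd_i
        z2ee = cK[4] * z1ee
        z2ei = cK[5] * z1ei
        z2ie = cK[6] * z1ie
        z2ii = cK[7] * z1ii
        r_E, r_I = ctx_deriv(y, P, z1ee, z1ei, z1ie, z1ii,
                             z2ee, z2ei, z2ie, z2ii,
                             mue_ext[i], mui_ext[i],
                             mug, sgg, r_t, v_t, tau_t, dy)
        for j in range(N_CTX):
            y[j] += dt * dy[j]
        # clamp synaptic means/variances to their physical ranges
        for j in range(3, 7):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        for j in range(7, 11):
            if y[j] < 0.0:
                y[j] = 0.0
        re_hist[ie] = r_E
        ri_hist[ii] = r_I
        ie = (ie + 1) % n_de
        ii = (ii + 1) % n_di
        if (i + 1) % dec == 0:
            k = (i + 1) // dec - 1
            if k < n_out:
                out[0, k] = r_E * 1e3
                out[1, k] = r_I * 1e3
                out[2, k] = y[2]
                out[3, k] = y[0]
            if not np.isfinite(y[0]):
                return (i + 1) * dt
    return -1.0


def _pack(params: CorticalParams):
    n = params.neuron
    P = np.array([params.J_EE, params.J_EI, params.J_IE, params.J_II,
                  params.tau_se, params.tau_si,
                  params.sigma_ext_E, params.sigma_ext_I,
                  n.a, n.E_A, n.tau_A, n.b, n.C_m, n.tau_m])
    cK = np.array([params.c_EE * params.K_E, params.c_EI * params.K_I,
                   params.c_IE * params.K_E, params.c_II * params.K_I,
                   params.c_EE, params.c_EI, params.c_IE, params.c_II])
    return P, cK


def initial_state(params: CorticalParams) -> np.ndarray:
    y = np.zeros(N_CTX)
    y[0] = params.mu_E_mvms
    y[1] = params.mu_I_mvms
    return y


def simulate_cortex(
    params: CorticalParams,
    grid: SimGrid,
    table: TransferTable | None = None,
    external_rate: np.ndarray | None = None,
    coupling: float = 1.0,
    initial: np.ndarray | None = None,
    rngs: dict | None = None,
):
    """Simulate the isolated cortical node.

    Parameters
    ----------
    external_rate : array, optional
        Excitatory rate input in Hz (e.g. a thalamic relay rate), entering
        the effective input rate of the excitatory population scaled by
        ``coupling``; one value per integration step or per output sample.

    Returns
    -------
    dict with ``t`` (ms), ``r_E``, ``r_I`` (Hz), ``I_A`` (pA), ``mu_f_E``
    (mV/ms) at ``dt_samp`` resolution.
    """
    table = table or build_transfer_table(params.neuron)
    P, cK = _pack(params)
    n = grid.n_steps

    if rngs is None:
        rngs = spawn_streams(grid.seed, ("TCR", "E", "I"))
    mue = ou_process(OUParams(params.mu_E_mvms, params.sigma_E, params.tau_ou),
                     grid, rngs["E"])
    mui = ou_process(OUParams(params.mu_I_mvms, params.sigma_I, params.tau_ou),
                     grid, rngs["I"])

    if external_rate is None:
        ext = np.zeros(n)
    else:
        ext = np.asarray(external_rate, dtype=float) * 1e-3 * coupling  # kHz
        if ext.size != n:
            ext = np.repeat(ext, max(1, n // ext.size))[:n]
        if ext.size < n:
            ext = np.pad(ext, (0, n - ext.size), mode="edge")

    y0 = initial_state(params) if initial is None else initial
    n_out = n // grid.decimation
    out = np.empty((4, n_out))
    t_fail = _run_cortex(y0, P, cK, grid.dt, n, grid.decimation,
                         delay_steps(params.d_E, grid.dt),
                         delay_steps(params.d_I, grid.dt),
                         mue, mui, ext,
                         table.mu_grid, table.sigma_grid,
                         table.r_table, table.V_table, table.tau_table,
                         out)
    if t_fail >= 0:
        raise FloatingPointError(f"cortical state diverged at t = {t_fail:.2f} ms")
    return {"t": grid.times(), "r_E": out[0], "r_I": out[1],
            "I_A": out[2], "mu_f_E": out[3]}
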