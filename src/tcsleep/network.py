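"""Full thalamocortical loop: cortical E-I node coupled to the thalamic node.

The cortical excitatory rate drives the AMPA inputs of both thalamic
populations (strength ``N_ctx_thal``) and the thalamic relay rate drives the
excitatory cortical population (strength ``N_thal_ctx``); both directions
use the same physiologically motivated conduction delay of 13 ms.  Rates are
exchanged in kHz internally (Hz at the API); the coupling strengths are the
free parameters of the model -- realistic values are unknown and the two
directions are expected to differ roughly tenfold, mirroring the roughly
tenfold difference in the nodes' maximum firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .numerics import OUParams, SimGrid, delay_steps, ou_process, spawn_streams
from .thalamus.model import ThalamicParams, firing_rate, steady_init, \
    thal_deriv, N_STATE as N_THAL
from .cortex.model import CorticalParams, ctx_deriv, initial_state, _pack, \
    N_CTX
from .cortex.transfer import TransferTable, build_transfer_table

__all__ = ["LoopConfig", "simulate_loop"]


@dataclass(frozen=True)
class LoopConfig:
    """Coupling of the thalamocortical loop (Fig-style motif).

    ``sigma_TCR``, ``sigma_E``, ``sigma_I`` override the per-node noise
    settings so a single object describes one experiment.
    """

    N_ctx_thal: float = 1.2   # cortex -> thalamus (both TCR and TRN)
    N_thal_ctx: float = 0.12  # thalamus (TCR) -> cortical E
    delay: float = 13.0       # ms, both directions
    sigma_TCR: float = 0.005  # OU noise on TCR synaptic input
    tau_ou_TCR: float = 5.0

    def __post_init__(self):
        if self.N_ctx_thal < 0 or self.N_thal_ctx < 0:
            raise ValueError("coupling strengths must be >= 0")
        if self.delay <= 0:
            raise ValueError("delay must be > 0")

    def with_(self, **kw) -> "LoopConfig":
        return replace(self, **kw)


@njit(cache=True)
def _run_loop(y_th0, P_th, y_cx0, P_cx, cK, dt, n_steps, dec,
              n_de, n_di, n_x, n_ctx_thal, n_thal_ctx,
              noise_tcr, mue_ext, mui_ext,
              mug, sgg, r_t, v_t, tau_t, out):
    y_th = y_th0.copy()
    y_cx = y_cx0.copy()
    d_th = np.empty(N_THAL)
    d_cx = np.empty(N_CTX)

    rmax = P_th[9]
    theta = P_th[10]
    siggain = P_th[11] / P_th[12]

    # initial rates for the history buffers
    r_tcr0 = rmax / (1.0 + np.exp(-(y_th[0] - theta) / siggain))
    r_E0, r_I0 = ctx_deriv(y_cx, P_cx, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                           mue_ext[0], mui_ext[0], mug, sgg, r_t, v_t, tau_t,
                           d_cx)
    re_hist = np.full(n_de, r_E0)
    ri_hist = np.full(n_di, r_I0)
    rext_e = np.full(n_x, r_E0)      # cortical E rate history, 13 ms
    rext_tcr = np.full(n_x, r_tcr0)  # TCR rate history, 13 ms
    ie = 0
    ii = 0
    ix = 0
    n_out = n_steps // dec
    for i in range(n_steps):
        # cortex -> thalamus: delayed excitatory rate into both AMPA inputs
        ext_th = n_ctx_thal * rext_e[ix]
        thal_deriv(y_th, P_th, ext_th, noise_tcr[i], d_th)

        # thalamus -> cortex: delayed TCR rate into the E population
        rd_e = re_hist[ie]
        rd_i = ri_hist[ii]
        ext_cx = n_thal_ctx * rext_tcr[ix]
        z1ee = cK[0] * (rd_e + ext_cx)
        z1ei = cK[1] * rd_i
        z1ie = cK[2] * rd_e
        z1ii = cK[3] * rd_i
        r_E, r_I = ctx_deriv(y_cx, P_cx, z1ee, z1ei, z1ie, z1ii,
                             cK[4] * z1ee, cK[5] * z1ei,
                             cK[6] * z1ie, cK[7] * z1ii,
                             mue_ext[i], mui_ext[i],
                             mug, sgg, r_t, v_t, tau_t, d_cx)

        for j in range(N_THAL):
            y_th[j] += dt * d_th[j]
        for j in range(N_CTX):
            y_cx[j] += dt * d_cx[j]
        for j in range(3, 7):
            if y_cx[j] < 0.0:
                y_cx[j] = 0.0
            elif y_cx[j] > 1.0:
                y_cx[j] = 1.0
        for j in range(7, 11):
            if y_cx[j] < 0.0:
                y_cx[j] = 0.0

        r_tcr = rmax / (1.0 + np.exp(-(y_th[0] - theta) / siggain))
        re_hist[ie] = r_E
        ri_hist[ii] = r_I
        rext_e[ix] = r_E
        rext_tcr[ix] = r_tcr
        ie = (ie + 1) % n_de
        ii = (ii + 1) % n_di
        ix = (ix + 1) % n_x

        if (i + 1) % dec == 0:
            k = (i + 1) // dec - 1
            if k < n_out:
                out[0, k] = r_E * 1e3
                out[1, k] = r_I * 1e3
                out[2, k] = y_th[0]
                out[3, k] = y_th[1]
                out[4, k] = y_cx[2]
            if not (np.isfinite(y_cx[0]) and np.isfinite(y_th[0])):
                return (i + 1) * dt
    return -1.0


def simulate_loop(
    cortex: CorticalParams,
    thal: ThalamicParams,
    loop: LoopConfig,
    grid: SimGrid,
    table: TransferTable | None = None,
):
    """Closed-loop simulation of the thalamocortical motif.

    Noise streams (TCR, E, I) are spawned from ``grid.seed``; with both
    coupling strengths at zero each node's trajectory is identical to its
    isolated simulation under the same master seed.

    Returns
    -------
    dict with ``t`` (ms) and ``r_E``, ``r_I``, ``r_TCR``, ``r_TRN`` (Hz),
    plus ``I_A`` (pA), at ``dt_samp`` resolution.
    """
    table = table or build_transfer_table(cortex.neuron)
    P_th = thal.to_array()
    P_cx, cK = _pack(cortex)
    n = grid.n_steps

    rngs = spawn_streams(grid.seed, ("TCR", "E", "I"))
    noise_tcr = ou_process(OUParams(0.0, loop.sigma_TCR, loop.tau_ou_TCR),
                           grid, rngs["TCR"])
    mue = ou_process(OUParams(cortex.mu_E_mvms, cortex.sigma_E, cortex.tau_ou),
                     grid, rngs["E"])
    mui = ou_process(OUParams(cortex.mu_I_mvms, cortex.sigma_I, cortex.tau_ou),
                     grid, rngs["I"])

    n_out = n // grid.decimation
    out = np.empty((5, n_out))
    t_fail = _run_loop(
        steady_init(thal), P_th, initial_state(cortex), P_cx, cK,
        grid.dt, n, grid.decimation,
        delay_steps(cortex.d_E, grid.dt), delay_steps(cortex.d_I, grid.dt),
        delay_steps(loop.delay, grid.dt),
        loop.N_ctx_thal, loop.N_thal_ctx,
        noise_tcr, mue, mui,
        table.mu_grid, table.sigma_grid,
        table.r_table, table.V_table, table.tau_table, out)
    if t_fail >= 0:
        raise FloatingPointError(f"loop state diverged at t = {t_fail:.2f} ms")
    return {
        "t": grid.times(),
        "r_E": out[0],
        "r_I": out[1],
        "r_TCR": firing_rate(out[2], thal),
        "r_TRN": firing_rate(out[3], thal),
        "I_A": out[4],
    }
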