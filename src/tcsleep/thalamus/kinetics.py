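"""Gating kinetics of the thalamic intrinsic currents.

The two-population thalamic mass model extends the membrane-potential
dynamics with Hodgkin-Huxley-type intrinsic currents that enable rebound
bursting: a T-type calcium current (I_T) in both populations and a
hyperpolarization-activated, calcium-modulated cation current (I_h) in the
relay population.  The kinetics below are the published ones of the source
conductance-based mass model (Schellenberger Costa et al. 2016):

* TCR T-current after Destexhe et al. 1998 (thalamocortical relay variant),
* TRN T-current after Destexhe et al. 1996 (reticular variant),
* I_h two-state (unbound/calcium-bound open) scheme after Destexhe et al.
  1996, with instantaneous calcium binding probability.

Voltages in mV, times in ms.  Inactivation time constants of the T-currents
carry the Q10 temperature correction 3^((36-24)/10) ~ 3.7371928 to 36 degC.
"""

import numpy as np
from numba import njit

_Q10 = 3.0 ** 1.2  # = 3.7371928...


@njit(cache=True)
def firing_rate(V, r_max, theta, sigma):
    """Sigmoidal voltage-to-rate transfer r_max / (1 + exp(-(V-theta)/sigma))."""
    return r_max / (1.0 + np.exp(-(V - theta) / sigma))


# ---- T-type calcium current, TCR (relay) variant --------------------------

@njit(cache=True)
def m_inf_T_t(V):
    return 1.0 / (1.0 + np.exp(-(V + 59.0) / 6.2))


@njit(cache=True)
def h_inf_T_t(V):
    return 1.0 / (1.0 + np.exp((V + 81.0) / 4.0))


@njit(cache=True)
def tau_h_T_t(V):
    return (30.8 + (211.4 + np.exp((V + 115.2) / 5.0))
            / (1.0 + np.exp((V + 86.0) / 3.2))) / _Q10


# ---- T-type calcium current, TRN (reticular) variant ----------------------

@njit(cache=True)
def m_inf_T_r(V):
    return 1.0 / (1.0 + np.exp(-(V + 52.0) / 7.4))


@njit(cache=True)
def h_inf_T_r(V):
    return 1.0 / (1.0 + np.exp((V + 80.0) / 5.0))


@njit(cache=True)
def tau_h_T_r(V):
    return (85.0 + 1.0 / (np.exp((V + 48.0) / 4.0)
                          + np.exp(-(V + 407.0) / 50.0))) / _Q10


# ---- hyperpolarization-activated cation current I_h (TCR only) ------------

@njit(cache=True)
def m_inf_h(V):
    return 1.0 / (1.0 + np.exp((V + 75.0) / 5.5))


@njit(cache=True)
def tau_m_h(V):
    return 20.0 + 1000.0 / (np.exp((V + 71.5) / 14.2)
                            + np.exp(-(V + 89.0) / 11.6))


@njit(cache=True)
def ca_binding(Ca, k1, k2, n_P):
    """Instantaneous fraction of calcium-bound regulator, P(Ca)."""
    c = k1 * Ca ** n_P
    return c / (c + k2)
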