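"""Precomputed transfer functions of an exponential integrate-and-fire population.

The mean-field cortical node replaces the spiking dynamics of a large AdEx
population by a linear-nonlinear cascade: for a mean input current mu (in
mV/ms) with white-noise standard deviation sigma (mV/sqrt(ms)), the
steady-state population rate r = Phi_r(mu, sigma), mean membrane voltage
Vbar = Phi_V(mu, sigma) and an effective input timescale tau = Phi_tau(mu,
sigma) are tabulated on a (mu, sigma) grid and looked up with bilinear
interpolation at run time (clamped at the grid boundary).

Phi_r and Phi_V are computed by steady-state threshold integration of the
Fokker-Planck equation (backward integration of the stationary density from
the spike threshold, with reinjection at the reset and a refractory
correction).  Phi_tau is obtained from the linear rate response r1(omega) to
a modulation of mu, computed with the same threshold-integration machinery,
by a least-squares fit of the low-pass model r1(0)/(1 + i omega tau).

Adaptation is not part of the table: the mean adaptation current shifts the
lookup argument, mu_E -> mu_E - IA/C.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict, replace

import numpy as np
from numba import njit, prange

__all__ = ["AdExNeuronParams", "TransferTable", "build_transfer_table",
           "lookup_transfer", "steady_state_rate_voltage", "rate_response"]


@dataclass(frozen=True)
class AdExNeuronParams:
    """Single AdEx neuron parameters underlying the cortical mass model.

    Defaults are the published set of the source mean-field cortical model
    (Cakan & Obermayer 2020).  Units: pF, nS, mV, ms, pA.
    """

    C_m: float = 200.0     # membrane capacitance (pF)
    g_L: float = 10.0      # leak conductance (nS)
    E_L: float = -65.0     # leak reversal (mV)
    Delta_T: float = 1.5   # exponential slope factor (mV)
    V_T: float = -50.0     # exponential threshold (mV)
    V_s: float = -40.0     # spike threshold (mV)
    V_r: float = -70.0     # reset potential (mV)
    T_ref: float = 1.5     # refractory time (ms)
    a: float = 0.0         # subthreshold adaptation (nS)
    E_A: float = -80.0     # adaptation reversal (mV)
    tau_A: float = 600.0   # adaptation timescale (ms)
    b: float = 30.0        # spike-triggered adaptation increment (pA)

    def __post_init__(self):
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be > 0")
        if self.V_r >= self.V_s:
            raise ValueError("V_r must be below V_s")
        if self.T_ref < 0:
            raise ValueError("T_ref must be >= 0")

    @property
    def tau_m(self) -> float:
        return self.C_m / self.g_L

    def key(self, extra: dict | None = None) -> str:
        payload = asdict(self)
        if extra:
            payload.update(extra)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:16]


@njit(cache=True, fastmath=True)
def _steady_density(mu, sigma, EL, DeltaT, VT, Vr, Vs, tau_m, Tref,
                    V, dV, p_out):
    """Backward threshold integration of the stationary density.

    Fills ``p_out`` with the unnormalized density (unit total efflux) and
    returns (rate in 1/ms, mean voltage in mV).
    """
    n = V.shape[0]
    inv_s2 = 2.0 / (sigma * sigma)
    p = 0.0
    p_out[n - 1] = 0.0
    ir = int(round((Vr - V[0]) / dV))
    norm = 0.0
    vsum = 0.0
    log_scale = 0.0  # running rescaling exponent against overflow at small sigma
    for k in range(n - 2, -1, -1):
        J = np.exp(-log_scale) if k >= ir else 0.0
        Vmid = V[k] + 0.5 * dV
        f = ((EL - Vmid) + DeltaT * np.exp((Vmid - VT) / DeltaT)) / tau_m
        A = inv_s2 * (f + mu)
        B = inv_s2 * J
        x = A * dV
        if x > 700.0:
            x = 700.0
        ex = np.exp(-x)
        if abs(x) > 1e-12:
            phi = (1.0 - ex) / x
        else:
            phi = 1.0
        p = p * ex + B * dV * phi
        if p > 1e150:
            p *= 1e-150
            norm *= 1e-150
            vsum *= 1e-150
            log_scale += 150.0 * np.log(10.0)
        p_out[k] = p
        norm += p
        vsum += V[k] * p
    norm *= dV
    vsum *= dV
    # true density integral is norm * exp(log_scale)
    log_norm = np.log(max(norm, 1e-300)) + log_scale
    if log_norm > 600.0:
        r = 0.0
        Vbar = vsum / max(norm, 1e-300)
    else:
        true_norm = np.exp(log_norm)
        r = 1.0 / (Tref + true_norm)
        Vbar = (vsum * np.exp(log_scale) + Tref * Vr) * r
    return r, Vbar


@njit(cache=True, fastmath=True)
def _rate_response(mu, sigma, EL, DeltaT, VT, Vr, Vs, tau_m, Tref,
                   V, dV, P0, omega):
    """Linear rate response r1(omega) to a modulation of mu (per unit mu)."""
    n = V.shape[0]
    inv_s2 = 2.0 / (sigma * sigma)
    ir = int(round((Vr - V[0]) / dV))
    # r-part: unit flux at threshold, reinjected at reset with refractory lag
    pr = 0.0 + 0.0j
    Jr = 1.0 + 0.0j
    # E-part: driven by the steady-state density
    pe = 0.0 + 0.0j
    Je = 0.0 + 0.0j
    reinj = np.exp(-1j * omega * Tref)
    for k in range(n - 2, -1, -1):
        Vmid = V[k] + 0.5 * dV
        f = ((EL - Vmid) + DeltaT * np.exp((Vmid - VT) / DeltaT)) / tau_m
        A = inv_s2 * (f + mu)
        x = A * dV
        if x > 700.0:
            x = 700.0
        ex = np.exp(-x)
        if abs(x) > 1e-12:
            phi = (1.0 - ex) / x
        else:
            phi = 1.0
        # flux update: dJ/dV = i omega p
        Jr_new = Jr + dV * 1j * omega * pr
        Je_new = Je + dV * 1j * omega * pe
        if k == ir:
            Jr_new = Jr_new - reinj
        Br = inv_s2 * Jr_new
        Be = inv_s2 * (Je_new - 0.5 * (P0[k] + P0[k + 1]))
        pr = pr * ex + Br * dV * phi
        pe = pe * ex + Be * dV * phi
        Jr = Jr_new
        Je = Je_new
    if abs(Jr) < 1e-300:
        return 0.0 + 0.0j
    return -Je / Jr


@njit(cache=True, parallel=True)
def _fill_tables(mu_grid, sigma_grid, EL, DeltaT, VT, Vr, Vs, tau_m, Tref,
                 V, dV, omegas, tau_candidates,
                 r_tab, v_tab, tau_tab):
    n_mu = mu_grid.shape[0]
    n_sig = sigma_grid.shape[0]
    n_w = omegas.shape[0]
    for js in prange(n_sig):
        p0 = np.empty(V.shape[0])
        resp = np.empty(n_w, dtype=np.complex128)
        for jm in range(n_mu):
            mu = mu_grid[jm]
            sig = sigma_grid[js]
            r, vb = _steady_density(mu, sig, EL, DeltaT, VT, Vr, Vs,
                                    tau_m, Tref, V, dV, p0)
            r_tab[jm, js] = r
            v_tab[jm, js] = vb
            if r < 1e-9:
                # effectively silent: input relaxes on the membrane timescale
                tau_tab[jm, js] = tau_m
                continue
            # normalized stationary density for the response calculation
            for k in range(V.shape[0]):
                p0[k] *= r
            for w in range(n_w):
                resp[w] = _rate_response(mu, sig, EL, DeltaT, VT, Vr, Vs,
                                         tau_m, Tref, V, dV, p0, omegas[w])
            r0 = _rate_response(mu, sig, EL, DeltaT, VT, Vr, Vs,
                                tau_m, Tref, V, dV, p0, 1e-4).real
            # least-squares fit of r0/(1 + i w tau) over the frequency set
            best = tau_candidates[0]
            best_err = 1e300
            for c in range(tau_candidates.shape[0]):
                tau = tau_candidates[c]
                err = 0.0
                for w in range(n_w):
                    model = r0 / (1.0 + 1j * omegas[w] * tau)
                    d = resp[w] - model
                    err += d.real * d.real + d.imag * d.imag
                if err < best_err:
                    best_err = err
                    best = tau
            tau_tab[jm, js] = best


@dataclass
class TransferTable:
    """Tabulated (mu, sigma) -> (rate Hz, Vbar mV, tau ms) maps."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    r_table: np.ndarray     # Hz
    V_table: np.ndarray     # mV
    tau_table: np.ndarray   # ms

    def __post_init__(self):
        if np.any(np.diff(self.mu_grid) <= 0) or np.any(np.diff(self.sigma_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        for t in (self.r_table, self.V_table, self.tau_table):
            if not np.all(np.isfinite(t)):
                raise ValueError("transfer tables contain non-finite values")

    def lookup(self, mu, sigma):
        """Bilinear interpolation, clamped to the grid boundary."""
        r = _interp2(self.mu_grid, self.sigma_grid, self.r_table,
                     np.atleast_1d(np.asarray(mu, dtype=float)),
                     np.atleast_1d(np.asarray(sigma, dtype=float)))
        v = _interp2(self.mu_grid, self.sigma_grid, self.V_table,
                     np.atleast_1d(np.asarray(mu, dtype=float)),
                     np.atleast_1d(np.asarray(sigma, dtype=float)))
        t = _interp2(self.mu_grid, self.sigma_grid, self.tau_table,
                     np.atleast_1d(np.asarray(mu, dtype=float)),
                     np.atleast_1d(np.asarray(sigma, dtype=float)))
        if np.isscalar(mu) or np.ndim(mu) == 0:
            return float(r[0]), float(v[0]), float(t[0])
        return r, v, t

    def save(self, path):
        np.savez_compressed(path, mu_grid=self.mu_grid,
                            sigma_grid=self.sigma_grid, r_table=self.r_table,
                            V_table=self.V_table, tau_table=self.tau_table)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            return cls(z["mu_grid"].copy(), z["sigma_grid"].copy(),
                       z["r_table"].copy(), z["V_table"].copy(),
                       z["tau_table"].copy())


@njit(cache=True)
def _interp2(mu_grid, sigma_grid, table, mu, sigma):
    out = np.empty(mu.shape[0])
    for i in range(mu.shape[0]):
        out[i] = _interp2_scalar(mu_grid, sigma_grid, table, mu[i], sigma[i])
    return out


@njit(cache=True, inline="always")
def _interp2_scalar(mu_grid, sigma_grid, table, mu, sigma):
    nm = mu_grid.shape[0]
    ns = sigma_grid.shape[0]
    if mu <= mu_grid[0]:
        im, wm = 0, 0.0
    elif mu >= mu_grid[nm - 1]:
        im, wm = nm - 2, 1.0
    else:
        im = np.searchsorted(mu_grid, mu) - 1
        wm = (mu - mu_grid[im]) / (mu_grid[im + 1] - mu_grid[im])
    if sigma <= sigma_grid[0]:
        js, ws = 0, 0.0
    elif sigma >= sigma_grid[ns - 1]:
        js, ws = ns - 2, 1.0
    else:
        js = np.searchsorted(sigma_grid, sigma) - 1
        ws = (sigma - sigma_grid[js]) / (sigma_grid[js + 1] - sigma_grid[js])
    return ((1 - wm) * (1 - ws) * table[im, js]
            + wm * (1 - ws) * table[im + 1, js]
            + (1 - wm) * ws * table[im, js + 1]
            + wm * ws * table[im + 1, js + 1])


def lookup_transfer(table: TransferTable, mu_eff, sigma):
    """(rate Hz, mean voltage mV, effective timescale ms) at (mu_eff, sigma)."""
    return table.lookup(mu_eff, sigma)


def steady_state_rate_voltage(neuron: AdExNeuronParams, mu: float, sigma: float,
                              dV: float = 0.01, V_lb: float = -200.0):
    """Single-point steady-state (rate Hz, Vbar mV) by threshold integration."""
    n = int(round((neuron.V_s - V_lb) / dV)) + 1
    V = V_lb + dV * np.arange(n)
    p = np.empty(n)
    r, vb = _steady_density(mu, sigma, neuron.E_L, neuron.Delta_T, neuron.V_T,
                            neuron.V_r, neuron.V_s, neuron.tau_m, neuron.T_ref,
                            V, dV, p)
    return r * 1e3, vb


def rate_response(neuron: AdExNeuronParams, mu: float, sigma: float,
                  freq_hz: float, dV: float = 0.01, V_lb: float = -200.0):
    """Linear rate response (complex, per unit mu) at one frequency."""
    n = int(round((neuron.V_s - V_lb) / dV)) + 1
    V = V_lb + dV * np.arange(n)
    p = np.empty(n)
    r, _ = _steady_density(mu, sigma, neuron.E_L, neuron.Delta_T, neuron.V_T,
                           neuron.V_r, neuron.V_s, neuron.tau_m, neuron.T_ref,
                           V, dV, p)
    p *= r
    return _rate_response(mu, sigma, neuron.E_L, neuron.Delta_T, neuron.V_T,
                          neuron.V_r, neuron.V_s, neuron.tau_m, neuron.T_ref,
                          V, dV, p, 2.0 * np.pi * freq_hz * 1e-3)


def _cache_dir() -> str:
    base = os.environ.get("TCSLEEP_CACHE",
                          os.path.join(os.path.expanduser("~"), ".cache", "tcsleep"))
    os.makedirs(base, exist_ok=True)
    return base


def build_transfer_table(
    neuron: AdExNeuronParams | None = None,
    mu_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    dV: float = 0.02,
    V_lb: float = -200.0,
    fit_freqs_hz: tuple = (1.0, 3.0, 7.0, 15.0, 30.0, 60.0),
    cache: bool = True,
) -> TransferTable:
    """Build (or load from cache) the transfer table for a neuron parameter set.

    The default grid spans mu in [-3, 7] mV/ms (400 points) and sigma in
    [0.25, 5] mV/sqrt(ms) (40 points), covering the dynamical regimes of the
    cortical node with room for synaptic and adaptation shifts.
    """
    neuron = neuron or AdExNeuronParams()
    if mu_grid is None:
        mu_grid = np.linspace(-3.0, 7.0, 400)
    if sigma_grid is None:
        sigma_grid = np.linspace(0.25, 5.0, 40)
    mu_grid = np.asarray(mu_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)

    key = neuron.key({"mu": mu_grid.tolist(), "sig": sigma_grid.tolist(),
                      "dV": dV, "V_lb": V_lb, "freqs": list(fit_freqs_hz)})
    path = os.path.join(_cache_dir(), f"transfer_{key}.npz")
    if cache and os.path.exists(path):
        return TransferTable.load(path)

    n = int(round((neuron.V_s - V_lb) / dV)) + 1
    V = V_lb + dV * np.arange(n)
    omegas = 2.0 * np.pi * np.asarray(fit_freqs_hz) * 1e-3  # rad/ms
    tau_candidates = np.concatenate([[1e-3], np.geomspace(0.05, 200.0, 240)])
    r_tab = np.empty((mu_grid.size, sigma_grid.size))
    v_tab = np.empty_like(r_tab)
    tau_tab = np.empty_like(r_tab)
    _fill_tables(mu_grid, sigma_grid, neuron.E_L, neuron.Delta_T, neuron.V_T,
                 neuron.V_r, neuron.V_s, neuron.tau_m, neuron.T_ref,
                 V, dV, omegas, tau_candidates, r_tab, v_tab, tau_tab)
    r_tab *= 1e3  # 1/ms -> Hz
    table = TransferTable(mu_grid, sigma_grid, r_tab, v_tab, tau_tab)
    if cache:
        table.save(path)
    return table
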