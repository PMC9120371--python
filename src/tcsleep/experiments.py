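"""Computational experiments: parameter sweeps and event-locked statistics.

Sweeps reproduce the model's dynamical maps (spindle density over the
thalamic conductance plane, cortical state-space maps over the background
currents, coupling-strength maps of the full loop) as long-format tables.
Event-locked tools quantify the slow-oscillation/spindle timing: DOWN-state
detection, event-triggered averages, delay histograms and circular phase
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .numerics import SimGrid, OUParams, TRANSIENT_MS
from .thalamus.model import ThalamicParams, simulate_thalamus
from .cortex.model import CorticalParams, simulate_cortex
from .cortex.transfer import build_transfer_table, TransferTable
from .network import LoopConfig, simulate_loop
from .detection import DetectorConfig, detect_spindles, spindle_density, \
    detect_down_states
from .synthetic import PacFixtureParams, generate_pac_signal, \
    generate_spindle_train  # noqa: F401  (fixture generators, re-exported)

__all__ = [
    "stft_matrix", "band_power", "dominant_frequency", "event_locked_average",
    "circular_phase_stats", "sweep_thalamus", "sweep_cortex", "sweep_loop",
    "down_state_spindle_delays", "spindle_band_peaks",
    "generate_pac_signal", "generate_spindle_train", "PacFixtureParams",
]


def stft_matrix(x: np.ndarray, fs: float, window_s: float = 2.0,
                step_s: float = 0.1) -> pd.DataFrame:
    """Short-time Fourier power of a rate series as a tidy matrix.

    Rows are frequencies (Hz), columns are window-center times (s); the 2 s
    default window matches the time-frequency panels of the locking
    analyses.
    """
    x = np.asarray(x, dtype=float)
    nper = int(window_s * fs)
    if len(x) < nper:
        raise ValueError("signal shorter than one STFT window")
    step = int(step_s * fs)
    f, t, S = sps.stft(x - x.mean(), fs=fs, nperseg=nper,
                       noverlap=nper - step, boundary=None, padded=False)
    return pd.DataFrame(np.abs(S) ** 2, index=np.round(f, 3),
                        columns=np.round(t, 3))


def band_power(x: np.ndarray, fs: float, band: tuple,
               nperseg_s: float = 4.0) -> float:
    """Mean Welch power spectral density over a frequency band."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band {band} outside Nyquist for fs={fs}")
    x = np.asarray(x, dtype=float)
    nper = int(nperseg_s * fs)
    if len(x) < nper:
        raise ValueError("signal shorter than one Welch window")
    f, P = sps.welch(x, fs=fs, nperseg=nper, window="hann")
    m = (f >= lo) & (f <= hi)
    return float(P[m].mean())


def dominant_frequency(x: np.ndarray, fs: float, fmin: float = 0.0,
                       fmax: float | None = None,
                       nperseg_s: float = 4.0) -> float:
    """Frequency of maximum Welch power (4 s Hann windows, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    nper = min(int(nperseg_s * fs), len(x))
    f, P = sps.welch(x - x.mean(), fs=fs, nperseg=nper, window="hann")
    if fmax is None:
        fmax = fs / 2
    m = (f >= fmin) & (f <= fmax)
    if not m.any() or P[m].max() <= 0:
        return float("nan")
    return float(f[m][np.argmax(P[m])])


def rate_amplitude(x: np.ndarray) -> float:
    """Max minus min rate (post-transient), the limit-cycle amplitude proxy."""
    return float(np.max(x) - np.min(x))


def event_locked_average(x: np.ndarray, fs: float, event_times_s: np.ndarray,
                         window_s: tuple = (-2.0, 2.0)):
    """Event-triggered mean and SEM of a signal.

    Events whose window does not fit inside the series are dropped.
    Returns (lags_s, mean, sem, n_used).
    """
    x = np.asarray(x, dtype=float)
    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    segs = []
    for te in np.asarray(event_times_s, dtype=float):
        k = int(round(te * fs))
        if k + i0 >= 0 and k + i1 < len(x):
            segs.append(x[k + i0:k + i1 + 1])
    if len(segs) < 2:
        raise ValueError("fewer than 2 usable events")
    segs = np.asarray(segs)
    mean = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / np.sqrt(len(segs))
    lags = np.arange(i0, i1 + 1) / fs
    return lags, mean, sem, len(segs)


def circular_phase_stats(phases: np.ndarray, n_bins: int = 18):
    """Circular mean, circular SD (sqrt(-2 ln R)) and phase histogram."""
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("empty input")
    z = np.mean(np.exp(1j * ph))
    R = min(np.abs(z), 1.0)
    mean = float(np.angle(z))
    sd = float(np.sqrt(max(-2.0 * np.log(R), 0.0))) if R > 0 else float("inf")
    hist, edges = np.histogram(ph, bins=n_bins, range=(-np.pi, np.pi))
    return {"mean": mean, "sd": sd, "R": float(R),
            "hist": hist, "bin_edges": edges}


def spindle_band_peaks(x: np.ndarray, fs: float,
                       config: DetectorConfig | None = None) -> np.ndarray:
    """Times (s) of the sigma-envelope maximum of each detected spindle."""
    return np.array([e.peak_time for e in detect_spindles(x, fs, config)])


def down_state_spindle_delays(r_e: np.ndarray, spindle_peaks_s: np.ndarray,
                              fs: float = 100.0,
                              max_delay_s: float = 1.5) -> np.ndarray:
    """Delay from each DOWN-state midpoint to the next spindle peak.

    Only DOWN states followed by a spindle peak within ``max_delay_s`` are
    counted ("spindle-followed" DOWN states).
    """
    downs = detect_down_states(r_e, fs)
    peaks = np.sort(np.asarray(spindle_peaks_s, dtype=float))
    delays = []
    for d in downs:
        i = np.searchsorted(peaks, d.midpoint)
        if i < len(peaks) and peaks[i] - d.midpoint <= max_delay_s:
            delays.append(peaks[i] - d.midpoint)
    return np.asarray(delays)


# ---------------------------------------------------------------------------
# parameter sweeps (long-format tables, one row per grid point)

def _post(out, key, transient_ms=TRANSIENT_MS):
    m = out["t"] > transient_ms
    return out[key][m]


def sweep_thalamus(
    g_LK_values: np.ndarray,
    g_h_values: np.ndarray,
    sigma_values: np.ndarray = (0.0,),
    duration: float = 65000.0,
    seed: int | None = 0,
    base: ThalamicParams | None = None,
    detector: DetectorConfig | None = None,
    external_rate_hz: float = 0.0,
) -> pd.DataFrame:
    """Spindle density over the (g_LK, g_h) conductance plane.

    Spindles are counted on the TCR rate (the population that projects to
    cortex).  A constant external excitatory rate (Hz) can be applied to
    both populations to mimic tonic cortical drive.
    """
    base = base or ThalamicParams()
    rows = []
    for sig in np.atleast_1d(sigma_values):
        for glk in np.atleast_1d(g_LK_values):
            for gh in np.atleast_1d(g_h_values):
                p = base.with_(g_LK=float(glk), g_h=float(gh))
                grid = SimGrid(duration=duration, seed=seed)
                ou = OUParams(0.0, float(sig), 5.0) if sig > 0 else None
                ext = (np.full(1, external_rate_hz)
                       if external_rate_hz else None)
                try:
                    out = simulate_thalamus(p, grid, ou=ou, external_rate=ext)
                except FloatingPointError:
                    rows.append({"g_LK": glk, "g_h": gh, "sigma": sig,
                                 "spindles_per_second": np.nan,
                                 "mean_duration": np.nan})
                    continue
                r = _post(out, "r_TCR")
                ev = detect_spindles(r, grid.fs, detector)
                dens = spindle_density(ev, len(r) / grid.fs)
                rows.append({
                    "g_LK": glk, "g_h": gh, "sigma": sig,
                    "spindles_per_second": dens["per_second"],
                    "mean_duration": (np.mean([e.duration for e in ev])
                                      if ev else np.nan),
                })
    return pd.DataFrame(rows)


def sweep_cortex(
    mu_E_values: np.ndarray,
    mu_I_values: np.ndarray,
    duration: float = 20000.0,
    seed: int | None = 0,
    base: CorticalParams | None = None,
    table: TransferTable | None = None,
) -> pd.DataFrame:
    """Cortical state-space map over the background currents (nA)."""
    base = base or CorticalParams()
    table = table or build_transfer_table(base.neuron)
    rows = []
    for mui in np.atleast_1d(mu_I_values):
        for mue in np.atleast_1d(mu_E_values):
            p = base.with_(mu_E_drift=float(mue), mu_I_drift=float(mui))
            try:
                out = simulate_cortex(p, SimGrid(duration=duration, seed=seed),
                                      table=table)
            except FloatingPointError:
                rows.append({"mu_E": mue, "mu_I": mui, "max_rate": np.nan,
                             "dominant_freq": np.nan, "amplitude": np.nan})
                continue
            r = _post(out, "r_E")
            amp = rate_amplitude(r)
            rows.append({
                "mu_E": mue, "mu_I": mui,
                "max_rate": float(r.max()),
                "dominant_freq": (dominant_frequency(r, 100.0)
                                  if amp > 0.1 else np.nan),
                "amplitude": amp,
            })
    return pd.DataFrame(rows)


def sweep_loop(
    n_thal_ctx_values: np.ndarray,
    n_ctx_thal_values: np.ndarray,
    cortex: CorticalParams | None = None,
    thal: ThalamicParams | None = None,
    duration: float = 65000.0,
    seed: int | None = 0,
    table: TransferTable | None = None,
) -> pd.DataFrame:
    """Loop map over the two coupling strengths.

    Reports the cortical excitatory rate's amplitude and its mean band
    powers in the slow-oscillation (0.1-3 Hz) and fast-spindle (12-15 Hz)
    ranges, plus the cortical spindle density.
    """
    cortex = cortex or CorticalParams(mu_E_drift=0.56, mu_I_drift=0.4)
    thal = thal or ThalamicParams(g_LK=0.033)
    table = table or build_transfer_table(cortex.neuron)
    rows = []
    for nct in np.atleast_1d(n_ctx_thal_values):
        for ntc in np.atleast_1d(n_thal_ctx_values):
            loop = LoopConfig(N_ctx_thal=float(nct), N_thal_ctx=float(ntc),
                              sigma_TCR=0.0)
            try:
                out = simulate_loop(cortex, thal, loop,
                                    SimGrid(duration=duration, seed=seed),
                                    table=table)
            except FloatingPointError:
                rows.append({"N_thal_ctx": ntc, "N_ctx_thal": nct,
                             "amplitude": np.nan, "so_power": np.nan,
                             "spindle_power": np.nan,
                             "ctx_spindles_per_second": np.nan})
                continue
            r = _post(out, "r_E")
            ev = detect_spindles(r, 100.0, DetectorConfig.cortical())
            rows.append({
                "N_thal_ctx": ntc, "N_ctx_thal": nct,
                "amplitude": rate_amplitude(r),
                "so_power": band_power(r, 100.0, (0.1, 3.0)),
                "spindle_power": band_power(r, 100.0, (12.0, 15.0)),
                "ctx_spindles_per_second":
                    spindle_density(ev, len(r) / 100.0)["per_second"],
            })
    return pd.DataFrame(rows)
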