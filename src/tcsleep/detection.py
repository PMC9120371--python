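"""Sleep-spindle and DOWN-state detection on model rate time series.

The spindle detector follows the A7 approach: three sliding decision
streams -- relative sigma-band power, moving correlation between the
sigma-filtered and broadband signal, and moving RMS of the sigma-filtered
signal -- are thresholded and combined; contiguous supra-threshold segments
are merged and filtered by duration.  Signals are z-scored first so the
amplitude thresholds are unit-free (model rates are not EEG).

Two thresholds are adapted for mass-model output: the minimum duration can
be lowered from 0.5 to 0.3 s and the relative sigma-power threshold from
0.2 to 0.15 (used for cortical signals whose spindles are briefer); the
remaining constants keep the published A7-style defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

import mne

__all__ = ["DetectorConfig", "SpindleEvent", "detect_spindles",
           "spindle_density", "DownStateEvent", "detect_down_states"]


@dataclass(frozen=True)
class DetectorConfig:
    sigma_band: tuple = (12.0, 15.0)   # Hz
    broad_band: tuple = (1.0, 30.0)    # Hz, reference band for relative power
    min_duration: float = 0.5          # s (0.3 for cortical signals)
    max_duration: float = 2.5          # s
    rel_power_threshold: float = 0.2   # (0.15 for cortical signals)
    corr_threshold: float = 0.65       # moving correlation threshold
    rms_threshold_sd: float = 1.5      # moving-RMS threshold in SDs above mean
    corr_window: float = 0.3           # s
    corr_step: float = 0.1             # s
    stft_window: float = 2.0           # s, for relative power
    stft_step: float = 0.2             # s
    merge_gap: float = 0.5             # s, merge events closer than this
    min_streams: int = 3               # streams that must agree (AND rule)

    def __post_init__(self):
        if not (0 < self.min_duration < self.max_duration):
            raise ValueError("need 0 < min_duration < max_duration")
        for thr in (self.rel_power_threshold, self.corr_threshold,
                    self.rms_threshold_sd):
            if thr < 0:
                raise ValueError("thresholds must be >= 0")

    def with_(self, **kw) -> "DetectorConfig":
        return replace(self, **kw)

    @classmethod
    def cortical(cls) -> "DetectorConfig":
        """Variant for cortical rates: shorter spindles, lower power share."""
        return cls(min_duration=0.3, rel_power_threshold=0.15)


@dataclass(frozen=True)
class SpindleEvent:
    start: float          # s
    end: float            # s
    peak_time: float      # s, maximum of the sigma envelope
    duration: float       # s
    mean_frequency: float  # Hz
    peak_amplitude: float  # signal units (z-scored)

    def __post_init__(self):
        if not (self.start < self.peak_time <= self.end):
            raise ValueError("need start < peak_time <= end")


def _moving_windows(x, win, step):
    """Start indices of sliding windows fully inside x."""
    return range(0, max(len(x) - win + 1, 0), step)


def _interp_stream(values, centers, n, fs):
    t = np.arange(n) / fs
    return np.interp(t, centers, values, left=values[0], right=values[-1])


def detect_spindles(x: np.ndarray, fs: float = 100.0,
                    config: DetectorConfig | None = None) -> list[SpindleEvent]:
    """Detect spindles in a 1-D rate series sampled at ``fs`` (default 100 Hz).

    Returns a time-sorted list of non-overlapping events.  A flat signal or
    a signal with no supra-threshold segment yields an empty list.
    """
    cfg = config or DetectorConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < int(cfg.stft_window * fs) + 1:
        raise ValueError("signal shorter than the analysis window")
    sd = x.std()
    if sd == 0:
        return []
    z = (x - x.mean()) / sd

    lo, hi = cfg.sigma_band
    sig = mne.filter.filter_data(z, fs, lo, hi, verbose=False)
    blo, bhi = cfg.broad_band
    broad = mne.filter.filter_data(z, fs, blo, bhi, verbose=False)
    env = np.abs(sps.hilbert(sig))

    n = len(z)
    # stream 1: relative sigma power from a sliding spectrogram
    nper = int(cfg.stft_window * fs)
    step = int(cfg.stft_step * fs)
    f, tt, S = sps.stft(broad, fs=fs, nperseg=nper, noverlap=nper - step,
                        boundary=None, padded=False)
    P = np.abs(S) ** 2
    bb = (f >= blo) & (f <= bhi)
    ss = (f >= lo) & (f <= hi)
    tot = P[bb].sum(axis=0)
    tot[tot == 0] = np.inf
    relpow = P[ss].sum(axis=0) / tot
    relpow_t = _interp_stream(relpow, tt, n, fs)

    # streams 2 and 3: moving correlation and moving RMS (0.3 s / 0.1 s)
    win = int(cfg.corr_window * fs)
    stp = int(cfg.corr_step * fs)
    starts = list(_moving_windows(z, win, stp))
    corr = np.empty(len(starts))
    rms = np.empty(len(starts))
    for k, s0 in enumerate(starts):
        a = broad[s0:s0 + win]
        b = sig[s0:s0 + win]
        va, vb = a.std(), b.std()
        corr[k] = float(np.corrcoef(a, b)[0, 1]) if va > 0 and vb > 0 else 0.0
        rms[k] = np.sqrt(np.mean(b ** 2))
    centers = (np.asarray(starts) + win / 2) / fs
    corr_t = _interp_stream(corr, centers, n, fs)
    rms_t = _interp_stream(rms, centers, n, fs)
    rms_thresh = rms.mean() + cfg.rms_threshold_sd * rms.std()

    votes = ((relpow_t >= cfg.rel_power_threshold).astype(int)
             + (corr_t >= cfg.corr_threshold).astype(int)
             + (rms_t >= rms_thresh).astype(int))
    above = votes >= cfg.min_streams

    events = []
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    segs = edges.reshape(-1, 2)  # [start, end) index pairs
    # merge segments separated by less than merge_gap
    merged = []
    for s0, s1 in segs:
        if merged and (s0 - merged[-1][1]) / fs < cfg.merge_gap:
            merged[-1][1] = s1
        else:
            merged.append([s0, s1])
    for s0, s1 in merged:
        # refine the segment to the envelope's half-peak extent: the decision
        # streams are window-smeared, the envelope localises the burst
        ipk_abs = s0 + int(np.argmax(env[s0:s1]))
        half = 0.5 * env[ipk_abs]
        a = ipk_abs
        while a > s0 and env[a - 1] >= half:
            a -= 1
        b = ipk_abs + 1
        while b < s1 and env[b] >= half:
            b += 1
        s0, s1 = a, b
        dur = (s1 - s0) / fs
        if dur < cfg.min_duration or dur > cfg.max_duration:
            continue
        seg_env = env[s0:s1]
        ipk = int(np.argmax(seg_env))
        seg_sig = sig[s0:s1]
        # mean frequency: cycles between first and last zero crossing
        zc = np.flatnonzero(np.diff(np.signbit(seg_sig)))
        if len(zc) >= 2 and zc[-1] > zc[0]:
            mean_freq = ((len(zc) - 1) / 2.0) / ((zc[-1] - zc[0]) / fs)
        else:
            mean_freq = float("nan")
        events.append(SpindleEvent(
            start=s0 / fs,
            end=s1 / fs,
            peak_time=(s0 + ipk + 0.5) / fs,
            duration=dur,
            mean_frequency=mean_freq,
            peak_amplitude=float(seg_env[ipk]),
        ))
    return events


def spindle_density(events: list, duration_s: float) -> dict:
    """Spindles per second (and per minute) over a given analysed duration."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    n = len(events)
    return {"per_second": n / duration_s, "per_minute": 60.0 * n / duration_s}


@dataclass(frozen=True)
class DownStateEvent:
    start: float     # s
    end: float       # s
    midpoint: float  # s

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("need start < end")


def detect_down_states(r_e: np.ndarray, fs: float = 100.0,
                       rel_threshold: float = 0.25,
                       min_dwell: float = 0.1,
                       smooth_s: float = 0.1) -> list[DownStateEvent]:
    """DOWN states of a cortical excitatory rate series.

    The rate is first smoothed with a ``smooth_s`` moving average (removing
    the spindle-band ripple that rides on the slow oscillation); a DOWN
    state is then an interval where it stays below
    ``p5 + rel_threshold * (p95 - p5)`` (percentiles of the analysed series,
    a scale-free criterion) for at least ``min_dwell`` seconds.
    """
    r = np.asarray(r_e, dtype=float)
    if r.size == 0 or np.ptp(r) == 0:
        return []
    w = max(int(round(smooth_s * fs)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        r = np.convolve(r, kernel, mode="same")
    lo, hi = np.percentile(r, [5, 95])
    if hi - lo <= 1e-9 * max(abs(hi), 1.0):
        return []  # no UP/DOWN structure beyond isolated outliers
    thr = lo + rel_threshold * (hi - lo)
    below = r < thr
    edges = np.flatnonzero(np.diff(np.r_[0, below.astype(int), 0]))
    out = []
    for s0, s1 in edges.reshape(-1, 2):
        if (s1 - s0) / fs >= min_dwell:
            out.append(DownStateEvent(start=s0 / fs, end=s1 / fs,
                                      midpoint=(s0 + s1) / 2.0 / fs))
    return out
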