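"""Synthetic test signals with known ground truth.

Generators for (a) two-band signals with a prescribed phase-amplitude
modulation depth and preferred coupling phase, used to validate the
cross-frequency coupling statistics, and (b) trains of waxing-waning
sigma-band bursts on a noise background, used to validate the spindle
detector.  Both store their ground truth alongside the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PacFixtureParams", "generate_pac_signal", "generate_spindle_train"]


@dataclass(frozen=True)
class PacFixtureParams:
    """Parameters of the phase-amplitude-coupled fixture signal.

    The signal is
    ``A_s sin(2 pi f_s t) + A_f [1 + m cos(2 pi f_s t - phi0)] sin(2 pi f_f t)
    + noise``: the fast-band amplitude peaks where the slow cycle's phase
    equals ``phi0`` (cosine-phase convention, 0 = slow peak).
    """

    f_slow: float = 0.75     # Hz
    f_fast: float = 13.0     # Hz
    m: float = 0.9           # modulation depth in [0, 1]
    phi0: float = 0.0        # preferred phase (rad)
    A_slow: float = 1.0
    A_fast: float = 0.5
    noise_sd: float = 0.1
    duration: float = 120.0  # s
    fs: float = 100.0        # Hz
    seed: int | None = 0
    phase_diffusion: float = 0.4  # rad/sqrt(s) wander of the slow phase

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"modulation depth must be in [0,1], got {self.m}")
        if not self.f_slow < self.f_fast:
            raise ValueError("f_slow must be below f_fast")
        if self.phase_diffusion < 0:
            raise ValueError("phase_diffusion must be >= 0")


def generate_pac_signal(params: PacFixtureParams) -> dict:
    """Raw two-band signal with known phase-amplitude coupling.

    The slow component's phase wanders as a random walk (like the irregular,
    noise-timed slow oscillation of the model) while the fast-band envelope
    stays locked to that instantaneous phase, so the ground-truth modulation
    depth ``m`` and preferred phase ``phi0`` are preserved.  Setting
    ``phase_diffusion=0`` yields the strictly periodic variant (note that
    spectrum-preserving surrogates cannot null a strictly periodic
    modulation, so significance tests need the wandering default).

    Returns dict with ``t`` (s), ``x``, and the ground-truth ``m``/``phi0``.
    """
    p = params
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs
    rng = np.random.default_rng(p.seed)
    slow_phase = 2.0 * np.pi * p.f_slow * t
    if p.phase_diffusion > 0:
        wander = np.cumsum(rng.standard_normal(n)) * (
            p.phase_diffusion / np.sqrt(p.fs))
        slow_phase = slow_phase + wander
    envelope = p.A_fast * (1.0 + p.m * np.cos(slow_phase - p.phi0))
    x = (p.A_slow * np.cos(slow_phase)  # cosine convention: peak at phase 0
         + envelope * np.sin(2.0 * np.pi * p.f_fast * t)
         + p.noise_sd * rng.standard_normal(n))
    return {"t": t, "x": x, "m": p.m, "phi0": p.phi0, "fs": p.fs}


def generate_spindle_train(
    burst_times: np.ndarray,
    burst_duration: float = 0.6,
    carrier_hz: float = 13.0,
    amplitude: float = 10.0,
    noise_sd: float = 1.0,
    duration: float | None = None,
    fs: float = 100.0,
    seed: int | None = 0,
) -> dict:
    """Gaussian-envelope sigma-band bursts on a white-noise background.

    ``burst_times`` are burst centers in seconds and must be separated by at
    least ``burst_duration`` (no overlap).  ``burst_duration`` is the full
    width at half maximum of the Gaussian envelope.  ``amplitude`` is the
    envelope peak in units of the background SD.

    Returns dict with ``t``, ``x``, and the ground-truth event table
    (onsets/offsets at half maximum).
    """
    centers = np.sort(np.asarray(burst_times, dtype=float))
    if np.any(np.diff(centers) < burst_duration):
        raise ValueError("bursts overlap")
    if duration is None:
        duration = centers.max() + 5.0 if centers.size else 10.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = noise_sd * rng.standard_normal(n)
    sigma_env = burst_duration / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM
    for c in centers:
        env = amplitude * noise_sd * np.exp(-0.5 * ((t - c) / sigma_env) ** 2)
        x += env * np.sin(2.0 * np.pi * carrier_hz * (t - c))
    events = [{"onset": c - burst_duration / 2.0,
               "offset": c + burst_duration / 2.0,
               "peak": c} for c in centers]
    return {"t": t, "x": x, "fs": fs, "events": events,
            "carrier_hz": carrier_hz}
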