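"""Shared numerical machinery for the mass-model simulators.

Everything downstream runs on a common convention: time in milliseconds,
forward-Euler integration at a fine step ``dt`` (default 0.01 ms), and all
analyses operating on trajectories subsampled at ``dt_samp`` (default 10 ms,
i.e. a 100 Hz analysis sampling rate).  Stochastic drive is an
Ornstein-Uhlenbeck (OU) process that is pre-integrated on the ``dt`` grid and
then inserted into the model equations with zero-order hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimGrid",
    "OUParams",
    "ou_process",
    "delay_steps",
    "DelayBuffer",
    "euler_integrate",
    "spawn_streams",
    "discard_transient",
]

#: transient (ms) discarded before statistics are computed on any simulation
TRANSIENT_MS = 5000.0


@dataclass(frozen=True)
class SimGrid:
    """Integration grid: step, duration and output subsampling.

    Parameters
    ----------
    duration : float
        Simulated time in ms.
    dt : float
        Forward-Euler integration step in ms.
    dt_samp : float
        Output sampling step in ms; must be an integer multiple of ``dt``.
    seed : int or None
        Master RNG seed. ``None`` means noise-free runs are still
        reproducible and noisy runs draw a fresh seed.
    """

    duration: float
    dt: float = 0.01
    dt_samp: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        ratio = self.dt_samp / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"dt_samp={self.dt_samp} must be an integer multiple of dt={self.dt}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def decimation(self) -> int:
        """Number of integration steps per output sample."""
        return int(round(self.dt_samp / self.dt))

    @property
    def fs(self) -> float:
        """Sampling rate of the subsampled output in Hz."""
        return 1000.0 / self.dt_samp

    def times(self) -> np.ndarray:
        """Output sample times in ms (first sample at t = dt_samp)."""
        n = self.n_steps // self.decimation
        return (np.arange(1, n + 1)) * self.dt_samp


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck drive: dx = (mu - x)/tau dt + sigma dW.

    ``mu`` is the mean drift (model input units), ``sigma`` the noise
    amplitude (units of input/ms^{1/2}, printed as mV/ms^{3/2} for current
    drives) and ``tau`` the relaxation time in ms.
    """

    mu: float = 0.0
    sigma: float = 0.0
    tau: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("OU mu must be finite")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"OU sigma must be >= 0, got {self.sigma}")
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"OU tau must be > 0, got {self.tau}")


def ou_process(
    params: OUParams,
    grid: SimGrid,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pre-integrate an OU process on the integration grid.

    The process starts at its mean, ``x(0) = mu``, and is advanced with the
    Euler-Maruyama step ``x += (mu - x)/tau dt + sigma sqrt(dt) xi`` with
    standard-normal ``xi``.  Returns the series of length ``grid.n_steps``
    (one value per integration step, zero-order held by the models).
    """
    n = grid.n_steps
    x = np.empty(n)
    if params.sigma == 0.0:
        x.fill(params.mu)
        return x
    if rng is None:
        rng = np.random.default_rng(grid.seed)
    noise = rng.standard_normal(n)
    _ou_kernel(x, noise, params.mu, params.sigma, params.tau, grid.dt)
    return x


def _ou_kernel(out, noise, mu, sigma, tau, dt):
    # vectorized exact recursion is avoided on purpose: the models consume the
    # plain Euler-Maruyama path, matching the forward-Euler treatment of the
    # deterministic part
    x = mu
    a = dt / tau
    b = sigma * np.sqrt(dt)
    for i in range(noise.shape[0]):
        x = x + (mu - x) * a + b * noise[i]
        out[i] = x


try:  # jit the inner loop; plain Python fallback keeps results identical
    from numba import njit

    _ou_kernel = njit(cache=True)(_ou_kernel)
except ImportError:  # pragma: no cover
    pass


def spawn_streams(seed: int | None, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """One independent child RNG per noise source from a single master seed.

    Streams are keyed by name with a fixed spawn order, so adding a noise
    source never perturbs another source's draws.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def delay_steps(delay_ms: float, dt: float) -> int:
    """Delay expressed in integration steps, ``round(delay/dt)`` exactly."""
    if delay_ms < 0:
        raise ValueError("delay must be >= 0")
    return int(round(delay_ms / dt))


class DelayBuffer:
    """Ring buffer holding the last ``n_steps`` values of a scalar signal.

    The buffer is pre-filled with the initial value, so a node sitting at a
    fixed point stays there (no startup transient from artificial zeros).
    """

    def __init__(self, n_steps: int, initial: float = 0.0):
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.n_steps = n_steps
        self._buf = np.full(n_steps, float(initial))
        self._pos = 0

    def read(self) -> float:
        """Value stored ``n_steps`` pushes ago."""
        return self._buf[self._pos]

    def push(self, value: float) -> None:
        self._buf[self._pos] = value
        self._pos = (self._pos + 1) % self.n_steps


def euler_integrate(
    rhs,
    state0: np.ndarray,
    grid: SimGrid,
    delays: dict[str, DelayBuffer] | None = None,
    delayed_of=None,
) -> np.ndarray:
    """Generic forward-Euler loop for small (possibly delayed) systems.

    ``rhs(t, state, delayed)`` must return the state derivative; ``delayed``
    is a dict of the current delayed reads of the buffers in ``delays``.
    ``delayed_of(state)`` maps the state to the dict of values pushed into
    the buffers each step.  Returns the full trajectory at ``dt`` resolution,
    shape ``(n_steps + 1, len(state0))`` including the initial state.

    The production models use specialised jitted loops; this reference
    integrator backs the unit tests and small design studies.
    """
    state = np.asarray(state0, dtype=float).copy()
    n = grid.n_steps
    out = np.empty((n + 1, state.size))
    out[0] = state
    delays = delays or {}
    for k in range(n):
        delayed = {name: buf.read() for name, buf in delays.items()}
        deriv = np.asarray(rhs(k * grid.dt, state, delayed))
        if not np.all(np.isfinite(deriv)):
            raise FloatingPointError(
                f"non-finite derivative at t={k * grid.dt:.3f} ms"
            )
        state = state + grid.dt * deriv
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"state diverged at t={k * grid.dt:.3f} ms")
        if delays:
            pushes = delayed_of(state) if delayed_of else {}
            for name, buf in delays.items():
                buf.push(pushes[name])
        out[k + 1] = state
    return out


def discard_transient(t_ms: np.ndarray, *series: np.ndarray, transient_ms: float = TRANSIENT_MS):
    """Drop the initial transient from aligned time/series arrays."""
    keep = t_ms > transient_ms
    out = [t_ms[keep]] + [s[..., keep] if s.ndim > 1 else s[keep] for s in series]
    return tuple(out)
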