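"""Bistable stochastic network simulator.

Ground-truth dynamics with a known number of attractive states: ``N``
uncoupled units, each obeying the cubic Langevin equation

    dx_i = (1 - x_i^2) x_i dt + sqrt(2 sigma) dW_i ,

with stable equilibria at +/-1 and an unstable one at 0.  Gaussian noise
drives intermittent transitions between the two wells ("down"/"up" states),
and the network's attractor repertoire — the set of sign patterns of the
state vector — scales as ``2^N``.  Integration uses the stochastic Heun
(predictor-corrector) scheme with additive noise, the same Wiener increment
entering both stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SimConfig",
    "SimResult",
    "DEFAULT_NOISE_GRID",
    "drift",
    "heun_step",
    "simulate",
    "count_well_transitions",
]

#: Default low / mid / high noise amplitudes for the 9-scenario grid.
DEFAULT_NOISE_GRID: tuple[float, float, float] = (0.10, 0.20, 0.35)


@dataclass
class SimConfig:
    """Parameters of one bistable-network run.

    ``noise_sigma`` is the noise amplitude sigma; the per-node diffusion
    coefficient is ``g = sqrt(2 sigma)``.  ``x0`` defaults to a random draw
    from {-1, +1}^N using ``seed`` (starting inside an attractor avoids the
    unstable origin).  ``burn_in`` time units are simulated and discarded
    before recording starts (default 0).
    """

    n_vars: int
    noise_sigma: float
    dt: float = 0.01
    t_end: float = 2000.0
    seed: int = 0
    x0: np.ndarray | None = None
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ValueError("n_vars must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.t_end > self.dt:
            raise ValueError("t_end must exceed dt")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.x0 is not None:
            self.x0 = np.asarray(self.x0, dtype=float)
            if self.x0.shape != (self.n_vars,):
                raise ValueError(f"x0 must have shape ({self.n_vars},)")
            if not np.all(np.isfinite(self.x0)):
                raise ValueError("x0 must be finite")

    @property
    def n_samples(self) -> int:
        """Number of recorded samples M = round(t_end / dt)."""
        return int(round(self.t_end / self.dt))


@dataclass
class SimResult:
    """Simulated trajectories plus the configuration that produced them."""

    trajectory: np.ndarray  # (n_vars, n_samples)
    config: SimConfig = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.trajectory.shape[1]) * self.config.dt


def drift(state: np.ndarray) -> np.ndarray:
    """Deterministic drift f(x) = (1 - x^2) x, applied component-wise."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    return (1.0 - state**2) * state


def heun_step(
    state: np.ndarray, dt: float, noise_sigma: float, dW: np.ndarray
) -> np.ndarray:
    """One stochastic Heun update.

    Predictor ``x~ = x + f(x) dt + g dW`` followed by corrector
    ``x' = x + (f(x) + f(x~)) dt / 2 + g dW`` with ``g = sqrt(2 sigma)``.
    The caller supplies the Wiener increment ``dW`` (variance ``dt`` per
    component), which makes the arithmetic directly testable.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(state, dtype=float)
    dW = np.asarray(dW, dtype=float)
    g = np.sqrt(2.0 * noise_sigma)
    f0 = drift(state)
    noise = g * dW
    predictor = state + f0 * dt + noise
    f1 = (1.0 - predictor**2) * predictor
    return state + 0.5 * (f0 + f1) * dt + noise


@njit(cache=True)
def _heun_path(x0, dW, dt, g):  # pragma: no cover - exercised via simulate()
    n_steps, n = dW.shape
    out = np.empty((n, n_steps + 1))
    x = x0.copy()
    for i in range(n):
        out[i, 0] = x[i]
    for k in range(n_steps):
        for i in range(n):
            xi = x[i]
            f0 = (1.0 - xi * xi) * xi
            noise = g * dW[k, i]
            xp = xi + f0 * dt + noise
            f1 = (1.0 - xp * xp) * xp
            x[i] = xi + 0.5 * (f0 + f1) * dt + noise
            out[i, k + 1] = x[i]
    return out


def simulate(config: SimConfig) -> SimResult:
    """Integrate the bistable network and record M = round(t_end/dt) samples.

    Samples are taken at t = 0, dt, ..., (M-1) dt (after the optional
    burn-in).  Trajectories are bit-reproducible for a given config: the
    initial condition (when not given) and every Wiener increment are drawn
    from ``numpy.random.default_rng(config.seed)``.
    """
    rng = np.random.default_rng(config.seed)
    if config.x0 is not None:
        x0 = config.x0.astype(float)
    else:
        x0 = rng.choice(np.array([-1.0, 1.0]), size=config.n_vars)
    n_record = config.n_samples
    n_burn = int(round(config.burn_in / config.dt))
    n_steps = n_record - 1 + n_burn
    dW = rng.normal(0.0, np.sqrt(config.dt), size=(n_steps, config.n_vars))
    g = float(np.sqrt(2.0 * config.noise_sigma))
    path = _heun_path(x0, dW, config.dt, g)
    trajectory = np.ascontiguousarray(path[:, n_burn:])
    if not np.all(np.isfinite(trajectory)):
        raise FloatingPointError("simulation diverged (non-finite state)")
    return SimResult(trajectory=trajectory, config=config)


def count_well_transitions(trajectory: np.ndarray) -> np.ndarray:
    """Per-variable count of sign changes (down/up well switches).

    A sample exactly at 0 (measure zero under the SDE) counts as the
    positive well.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    signs = np.where(traj >= 0, 1.0, -1.0)
    return np.sum(signs[:, 1:] != signs[:, :-1], axis=1)
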