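"""Synthetic surrogate recordings with controlled latent complexity.

Each surrogate subject is built by simulating ``n_latent`` bistable
stochastic sources (module :mod:`mdflow.sim`), mixing them into
``n_channels`` observed channels through a random orthonormal mixing
matrix, and adding i.i.d. Gaussian observation noise.  The number of
latent sources sets the size of the metastable state repertoire (2^N sign
patterns), so cohorts with ``n_latent`` = 2/3/4 emulate the
rest/music/speech ordering of dynamical complexity.  With
``shared_drive=True`` the latent trajectory is generated from a common
drive seed while mixing and observation noise stay subject-specific,
planting the shared stimulus-driven structure that intersubject
correlation should detect.

The latent SDE is integrated at dt = 1/fs, i.e. one time unit of the
simulator corresponds to one second of recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .recording import Recording
from .sim import SimConfig, simulate

__all__ = ["FixtureConfig", "generate_subject", "generate_cohort"]

_MAX_MIXING_RETRIES = 8


@dataclass
class FixtureConfig:
    """Parameters of one surrogate subject recording."""

    n_channels: int = 8
    n_latent: int = 2
    noise_sigma: float = 0.2  # latent SDE noise amplitude
    obs_noise_sd: float = 0.2  # channel observation noise (latent units)
    mixing_seed: int = 0
    drive_seed: int = 0
    duration_s: float = 200.0
    fs: float = 100.0
    shared_drive: bool = False
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.n_channels < self.n_latent:
            raise ValueError("need n_channels >= n_latent")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


def _orthonormal_mixing(rng: np.random.Generator, c: int, n: int) -> np.ndarray:
    """Random C x N matrix with orthonormal columns (full rank by QR)."""
    for _ in range(_MAX_MIXING_RETRIES):
        a = rng.standard_normal((c, n))
        if np.linalg.matrix_rank(a) == n:
            q, r = np.linalg.qr(a)
            # fix a sign convention so the draw is deterministic
            q = q * np.sign(np.diag(r))
            return q[:, :n]
    raise RuntimeError("could not draw a full-rank mixing matrix")


def generate_subject(cfg: FixtureConfig) -> Recording:
    """One surrogate subject: mixed bistable latents + observation noise."""
    sim_cfg = SimConfig(
        n_vars=cfg.n_latent,
        noise_sigma=cfg.noise_sigma,
        dt=1.0 / cfg.fs,
        t_end=cfg.duration_s,
        seed=cfg.drive_seed,
    )
    latent = simulate(sim_cfg).trajectory  # (N, M)
    rng = np.random.default_rng(cfg.mixing_seed)
    mixing = _orthonormal_mixing(rng, cfg.n_channels, cfg.n_latent)
    data = mixing @ latent
    data += rng.normal(0.0, cfg.obs_noise_sd, size=data.shape)
    return Recording(data=data, fs=cfg.fs, condition=cfg.condition)


def generate_cohort(
    n_subjects: int,
    configs: dict[str, FixtureConfig],
    master_seed: int = 0,
) -> dict[str, list[Recording]]:
    """Matched cohort across conditions.

    ``configs`` maps condition label -> template config; all conditions
    must share duration and sampling rate.  Per-subject mixing and drive
    seeds are derived deterministically from ``master_seed``; under
    ``shared_drive`` the template's ``drive_seed`` is used unchanged for
    every subject of that condition.
    """
    if n_subjects < 1:
        raise ValueError("need at least 1 subject")
    durations = {(c.duration_s, c.fs) for c in configs.values()}
    if len(durations) != 1:
        raise ValueError(f"mismatched duration/fs across conditions: {durations}")
    rng = np.random.default_rng(master_seed)
    cohort: dict[str, list[Recording]] = {}
    for cond in sorted(configs):
        template = configs[cond]
        recs = []
        for _ in range(n_subjects):
            mixing_seed = int(rng.integers(0, 2**31 - 1))
            drive_seed = (
                template.drive_seed
                if template.shared_drive
                else int(rng.integers(0, 2**31 - 1))
            )
            cfg = replace(
                template,
                mixing_seed=mixing_seed,
                drive_seed=drive_seed,
                condition=cond,
            )
            recs.append(generate_subject(cfg))
        cohort[cond] = recs
    return cohort
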