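"""Latent embedding of multichannel recordings via independent component
analysis.

The manifold-density analysis operates on a 2- (default) or 3-dimensional
latent trajectory obtained by blind source separation of the observed
channels.  ICA is defined only up to sign, permutation and scale of the
components; downstream density-map correlations are invariant to all three,
but for reproducibility the components returned here are ordered by the
channel-space variance they explain and sign-fixed to non-negative skewness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .recording import Recording

__all__ = ["LatentTrajectory", "fit_ica"]


@dataclass
class LatentTrajectory:
    """d x M independent-component time courses (d in {2, 3})."""

    components: np.ndarray
    source_channels: list[str] = field(default_factory=list)
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.components.shape[0] not in (2, 3):
            raise ValueError(
                f"expected 2 or 3 components, got {self.components.shape[0]}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ValueError("components must be finite")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_samples(self) -> int:
        return self.components.shape[1]


def fit_ica(
    recording: Recording,
    n_components: int = 2,
    seed: int = 0,
    *,
    zscore: bool = True,
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 3,
    on_fail: str = "raise",
) -> LatentTrajectory:
    """Embed a recording into ``n_components`` independent components.

    Channels are z-scored (default), whitened, and unmixed with the
    fixed-point FastICA algorithm using the log-cosh (tanh) contrast.
    Components are ordered by descending variance explained in channel
    space (the squared norm of their mixing column) and sign-fixed so each
    time course has non-negative skewness.

    The fixed-point iteration occasionally stalls for an unlucky random
    initialization; up to ``n_restarts`` deterministic restarts with seeds
    derived from ``seed`` are attempted before giving up.  A source that is
    genuinely near-Gaussian (e.g. a metastable unit that never switched
    wells during a short recording) cannot be separated by the log-cosh
    contrast at all; ``on_fail="use_last"`` then accepts the final
    non-converged estimate — still a valid whitened projection — instead of
    raising, recording ``converged: False`` in the fit metadata.

    Raises
    ------
    ValueError
        If the recording has fewer channels than ``n_components``.
    RuntimeError
        If no restart converges and ``on_fail="raise"`` (default).
    """
    if on_fail not in ("raise", "use_last"):
        raise ValueError("on_fail must be 'raise' or 'use_last'")
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    if recording.n_channels < n_components:
        raise ValueError(
            f"need >= {n_components} channels, recording has {recording.n_channels}"
        )
    X = recording.data.T  # observations x variables
    if zscore:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            dead = [recording.channel_labels[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance channels cannot be z-scored: {dead}")
        X = (X - X.mean(axis=0)) / sd

    sources = None
    attempt_seed = seed
    for attempt in range(max(1, n_restarts)):
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            whiten="unit-variance",
            tol=tol,
            max_iter=max_iter,
            random_state=attempt_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(X)  # (M, d), unit variance
                break
            except ConvergenceWarning:
                attempt_seed = (seed + 7919 * (attempt + 1)) % (2**31 - 1)
    converged = sources is not None
    if not converged:
        if on_fail == "raise":
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations in any "
                f"of {n_restarts} restarts (tol={tol}); consider raising "
                "max_iter, relaxing tol, or on_fail='use_last'"
            )
        warnings.warn(
            "FastICA did not converge; using the final non-converged estimate",
            stacklevel=2,
        )
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            whiten="unit-variance",
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X)

    comps = sources.T.copy()
    # order by channel-space variance explained: squared norm of the mixing
    # column (source variances are all 1 under unit-variance whitening)
    explained = np.sum(ica.mixing_**2, axis=0)
    order = np.argsort(explained)[::-1]
    comps = comps[order]
    skew = stats.skew(comps, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    comps *= flip[:, None]
    comps -= comps.mean(axis=1, keepdims=True)

    meta = {
        "algorithm": "fastica",
        "fun": "logcosh",
        "whiten": "unit-variance",
        "tol": tol,
        "max_iter": max_iter,
        "n_iter": int(ica.n_iter_),
        "converged": converged,
        "seed": seed,
        "zscore": zscore,
        "explained_channel_variance": explained[order].tolist(),
    }
    return LatentTrajectory(
        components=comps,
        source_channels=list(recording.channel_labels),
        fit_metadata=meta,
    )
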