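"""Comparator metrics: threshold-crossing switching rate and sliding-window
dynamic functional connectivity (dFC).

The switching rate checks whether a complexity difference could be a mere
excursion-rate difference: each channel is z-scored, binarized at
``|z| > threshold`` and the state changes are counted.  The dFC analysis is
the established correlation-of-correlations benchmark against which the MDF
statistic is compared: per-window channel x channel Pearson matrices are
vectorized (strict upper triangle) and correlated across windows, and the
std of the resulting matrix plays the role of the complexity statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import WindowSpec, make_windows
from .recording import Recording

__all__ = [
    "SwitchingResult",
    "DFCMatrix",
    "switching_rate",
    "switching_curve",
    "dfc_matrix",
    "dfc_std",
    "DEFAULT_THRESHOLD_GRID",
]

#: Binarization thresholds 2.0 ... 3.0 SD in steps of 0.1 (11 values).
DEFAULT_THRESHOLD_GRID: np.ndarray = np.round(np.arange(2.0, 3.0 + 1e-9, 0.1), 10)


@dataclass
class SwitchingResult:
    per_channel_counts: np.ndarray
    mean_rate: float  # switches per second, averaged over channels
    threshold_sd: float
    excluded_channels: list[str] = field(default_factory=list)


def switching_rate(recording: Recording, threshold_sd: float = 2.5) -> SwitchingResult:
    """Mean rate of crossings of the ``|z| > threshold_sd`` boundary.

    Each channel is z-scored; the binary state is 1 while the channel is
    beyond the threshold; every change of the binary state between
    consecutive samples (entering or leaving the suprathreshold state)
    counts as one switch.  Two-sided by design: excursions of either sign
    are counted.  Zero-variance channels are excluded with a warning.
    """
    if not threshold_sd > 0:
        raise ValueError("threshold_sd must be > 0")
    data = recording.data
    sd = data.std(axis=1, ddof=0)
    keep = sd > 0
    excluded = [recording.channel_labels[i] for i in np.flatnonzero(~keep)]
    if excluded:
        warnings.warn(f"excluding zero-variance channels: {excluded}", stacklevel=2)
    if not np.any(keep):
        raise ValueError("all channels have zero variance")
    z = (data[keep] - data[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    state = np.abs(z) > threshold_sd
    counts = np.sum(state[:, 1:] != state[:, :-1], axis=1)
    duration = recording.duration
    return SwitchingResult(
        per_channel_counts=counts,
        mean_rate=float(np.mean(counts / duration)),
        threshold_sd=float(threshold_sd),
        excluded_channels=excluded,
    )


def switching_curve(
    recording: Recording, thresholds: np.ndarray = DEFAULT_THRESHOLD_GRID
) -> dict[float, SwitchingResult]:
    """Switching rate over a grid of thresholds (default 2–3 SD, step 0.1)."""
    return {float(t): switching_rate(recording, float(t)) for t in thresholds}


@dataclass
class DFCMatrix:
    """Windows x windows correlation matrix of windowed FC patterns."""

    values: np.ndarray
    window_spec: WindowSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("dFC must be symmetric")
        if np.any(np.abs(np.diag(v) - 1.0) > 1e-9):
            raise ValueError("dFC diagonal must be 1")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def dfc_matrix(recording: Recording, spec: WindowSpec) -> DFCMatrix:
    """Dynamic functional connectivity matrix.

    Per window, the channel x channel Pearson FC matrix is computed; entry
    (i, j) of the dFC is the Pearson correlation between the vectorized
    strict upper triangles of FC(i) and FC(j).

    Requires >= 3 channels: with 2 channels each FC has a single
    off-diagonal value and the correlation between FC vectors is undefined.
    """
    c = recording.n_channels
    if c < 3:
        raise ValueError("dFC needs >= 3 channels")
    starts = make_windows(recording.n_samples, spec)
    iu = np.triu_indices(c, k=1)
    fc_vecs = np.empty((len(starts), len(iu[0])))
    for w, start in enumerate(starts):
        seg = recording.data[:, start : start + spec.length_samples]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            ch = recording.channel_labels[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(
                f"zero-variance channel '{ch}' in window {w} (start {start})"
            )
        fc_vecs[w] = np.corrcoef(seg)[iu]
    xc = fc_vecs - fc_vecs.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    if np.any(norms == 0):
        w = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"constant FC pattern in window {w}: dFC undefined")
    xc /= norms[:, None]
    vals = np.clip(xc @ xc.T, -1.0, 1.0)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return DFCMatrix(values=vals, window_spec=spec)


def dfc_std(d: DFCMatrix | np.ndarray, ddof: int = 0) -> float:
    """Population std of the strict upper triangle of the dFC matrix."""
    v = d.values if isinstance(d, DFCMatrix) else np.asarray(d, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return float(np.std(v[np.triu_indices(v.shape[0], k=1)], ddof=ddof))
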