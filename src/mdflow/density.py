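"""Sliding windows and smoothed occupancy density maps in latent space.

Each time window of the latent trajectory is turned into a d-dimensional
histogram (128 bins per dimension by default) on a grid fixed by the
component ranges of the *whole* recording, smoothed with a Gaussian kernel
(sd 8 bins by default, reflect boundary, truncated at 4 sd), and normalized
to unit total mass.  These density maps are the objects whose pairwise
correlations form the MDF matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .embed import LatentTrajectory

__all__ = [
    "WindowSpec",
    "DensityMap",
    "make_windows",
    "compute_bounds",
    "density_map",
    "density_stack",
]

GAUSS_TRUNCATE = 4.0  # kernel support in standard deviations


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in samples: length L, slide s."""

    length_samples: int
    slide_samples: int

    def __post_init__(self) -> None:
        if self.length_samples < 2:
            raise ValueError("window length must be >= 2 samples")
        if self.slide_samples < 1:
            raise ValueError("slide must be >= 1 sample")

    @classmethod
    def from_seconds(cls, length_s: float, slide_s: float, fs: float) -> "WindowSpec":
        """Convert second-valued window parameters via round(x * fs)."""
        return cls(int(round(length_s * fs)), int(round(slide_s * fs)))


@dataclass
class DensityMap:
    """Smoothed, unit-mass occupancy histogram of one window."""

    grid: np.ndarray
    bin_edges: list[np.ndarray]
    smooth_sd_bins: float

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("density map entries must be non-negative")
        if abs(float(self.grid.sum()) - 1.0) > 1e-9:
            raise ValueError("density map must sum to 1")


def make_windows(n_samples: int, spec: WindowSpec) -> np.ndarray:
    """Start indices 0, s, 2s, ... of fully contained windows.

    A trailing partial window is dropped; W = floor((M - L)/s) + 1.
    """
    L, s = spec.length_samples, spec.slide_samples
    if n_samples < L:
        raise ValueError(f"n_samples={n_samples} shorter than window L={L}")
    n_win = (n_samples - L) // s + 1
    return np.arange(n_win) * s


def compute_bounds(latent: LatentTrajectory | np.ndarray) -> np.ndarray:
    """Per-dimension (min, max) over all time points, shape (d, 2).

    The same bounds are used for every window so that maps live on a common
    grid.
    """
    comps = latent.components if isinstance(latent, LatentTrajectory) else np.atleast_2d(latent)
    bounds = np.stack([comps.min(axis=1), comps.max(axis=1)], axis=1)
    if np.any(bounds[:, 0] == bounds[:, 1]):
        dims = np.flatnonzero(bounds[:, 0] == bounds[:, 1]).tolist()
        raise ValueError(f"degenerate bounds (min == max) on dimension(s) {dims}")
    return bounds


def _bin_edges(bounds: np.ndarray, n_bins: int) -> list[np.ndarray]:
    return [np.linspace(lo, hi, n_bins + 1) for lo, hi in bounds]


def _bin_indices(comps: np.ndarray, bounds: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index per dimension; right-most edge inclusive."""
    lo = bounds[:, 0][:, None]
    hi = bounds[:, 1][:, None]
    idx = np.floor((comps - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def density_map(
    latent: LatentTrajectory | np.ndarray,
    window: tuple[int, int],
    bounds: np.ndarray | None = None,
    n_bins: int = 128,
    smooth_sd: float = 8.0,
) -> DensityMap:
    """Smoothed, normalized density map of one window ``(start, L)``.

    ``bounds`` defaults to the full-trajectory component ranges and must be
    identical across windows of the same recording.
    """
    comps = latent.components if isinstance(latent, LatentTrajectory) else np.atleast_2d(latent)
    start, L = window
    if start < 0 or start + L > comps.shape[1]:
        raise ValueError(
            f"window [{start}, {start + L}) outside data of length {comps.shape[1]}"
        )
    if bounds is None:
        bounds = compute_bounds(comps)
    else:
        bounds = np.asarray(bounds, dtype=float)
        if np.any(bounds[:, 0] >= bounds[:, 1]):
            raise ValueError("degenerate bounds (min >= max)")
    stack = density_stack(comps, np.array([start]), L, bounds, n_bins, smooth_sd)
    return DensityMap(
        grid=stack[0],
        bin_edges=_bin_edges(bounds, n_bins),
        smooth_sd_bins=float(smooth_sd),
    )


@lru_cache(maxsize=8)
def _smoothing_matrix(n_bins: int, smooth_sd: float) -> np.ndarray:
    """1-D Gaussian smoothing as an n x n matrix.

    Kernel of radius ``int(truncate * sd + 0.5)`` with weights
    ``exp(-k^2 / (2 sd^2))`` normalized to unit sum; out-of-range taps are
    folded back by half-sample symmetric ("reflect") boundary handling.
    Matches ``scipy.ndimage.gaussian_filter1d(mode='reflect')``, but as a
    matrix it applies to a whole stack of maps in one GEMM.
    """
    radius = int(GAUSS_TRUNCATE * smooth_sd + 0.5)
    k = np.arange(-radius, radius + 1)
    weights = np.exp(-0.5 * (k / smooth_sd) ** 2)
    weights /= weights.sum()
    K = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        for off, w in zip(k, weights):
            j = i + off
            # reflect: ..., 2, 1, 0 | 0, 1, 2, ... | n-1, n-2, ...
            while j < 0 or j >= n_bins:
                if j < 0:
                    j = -1 - j
                else:
                    j = 2 * n_bins - 1 - j
            K[i, j] += w
    return K


def _smooth_stack(maps: np.ndarray, smooth_sd: float) -> np.ndarray:
    """Separable Gaussian smoothing of a (W, n, ..., n) stack of maps."""
    if smooth_sd <= 0:
        return maps
    d = maps.ndim - 1
    n_bins = maps.shape[-1]
    K = _smoothing_matrix(n_bins, float(smooth_sd))
    for axis in range(1, d + 1):
        moved = np.ascontiguousarray(np.moveaxis(maps, axis, -1))
        shape = moved.shape
        smoothed = moved.reshape(-1, n_bins) @ K.T
        maps = np.moveaxis(smoothed.reshape(shape), -1, axis)
    return np.ascontiguousarray(maps)


def density_stack(
    comps: np.ndarray,
    starts: np.ndarray,
    length: int,
    bounds: np.ndarray,
    n_bins: int = 128,
    smooth_sd: float = 8.0,
) -> np.ndarray:
    """All window density maps at once, shape (W, n_bins, ..., n_bins).

    Histogramming uses a flat bin index + bincount per window; smoothing is
    one separable Gaussian pass over the whole stack; each map is then
    normalized to unit mass.
    """
    d, m = comps.shape
    idx = _bin_indices(comps, bounds, n_bins)
    flat = idx[0]
    for k in range(1, d):
        flat = flat * n_bins + idx[k]
    n_cells = n_bins**d
    maps = np.empty((len(starts), n_cells), dtype=float)
    for w, start in enumerate(starts):
        maps[w] = np.bincount(flat[start : start + length], minlength=n_cells)
    maps = maps.reshape((len(starts),) + (n_bins,) * d)
    maps = _smooth_stack(maps, smooth_sd)
    np.clip(maps, 0.0, None, out=maps)  # guard tiny negative FP residue
    totals = maps.reshape(len(starts), -1).sum(axis=1)
    maps /= totals.reshape((-1,) + (1,) * d)
    return maps
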