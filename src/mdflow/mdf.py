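"""The Manifold Density Flow (MDF) matrix and its complexity statistic.

The MDF matrix is the windows x windows Pearson-correlation matrix of the
smoothed latent-space density maps: entry (i, j) measures how similarly the
system explored the latent manifold during windows i and j.  The standard
deviation of its strict upper triangle is the complexity statistic — richer
dynamics, with more attractive states and smoother transitions among them,
yield a more uniform MDF and hence a *lower* std.

Two surfaces are provided: functional ops (:func:`mdf_matrix`,
:func:`mdf_std`, :func:`complexity_profile`) and a model/results pair
(:class:`ManifoldDensityFlow` / :class:`MDFResults`) that runs the full
embed -> density -> correlate pipeline from a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import WindowSpec, compute_bounds, density_stack, make_windows
from .embed import LatentTrajectory, fit_ica
from .recording import Recording

__all__ = [
    "MDFMatrix",
    "mdf_matrix",
    "mdf_std",
    "mdf_mean",
    "complexity_profile",
    "ManifoldDensityFlow",
    "MDFResults",
]


@dataclass
class MDFMatrix:
    """Windows x windows correlation matrix of density maps."""

    values: np.ndarray
    window_starts: np.ndarray
    window_spec: WindowSpec
    density_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MDF values must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("MDF must be symmetric")
        if np.any(np.abs(np.diag(v) - 1.0) > 1e-9):
            raise ValueError("MDF diagonal must be 1")
        if np.any(v < -1 - 1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("MDF entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector."""
        iu = np.triu_indices(self.n_windows, k=1)
        return self.values[iu]


def _pearson_rows(x: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Row-by-row Pearson correlation matrix (rows = observations vectors).

    ``dtype=np.float32`` halves the cost of the large windows x windows
    GEMM (relative error ~1e-5, negligible against replicate variability);
    the default keeps full double precision.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance density map(s) in window(s) {bad.tolist()}: "
            "cannot correlate a constant map"
        )
    xc /= norms[:, None]
    xc = np.ascontiguousarray(xc, dtype=dtype)
    c = (xc @ xc.T).astype(np.float64)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def mdf_matrix(
    latent: LatentTrajectory | np.ndarray,
    spec: WindowSpec,
    n_bins: int = 128,
    smooth_sd: float = 8.0,
    bounds: np.ndarray | None = None,
    corr_dtype=np.float64,
) -> MDFMatrix:
    """Compute the MDF matrix of a latent trajectory.

    Density-map bounds default to the component ranges over the whole
    trajectory, identical for every window.  ``corr_dtype=np.float32``
    speeds up the correlation stage for long recordings (see
    :func:`_pearson_rows`).
    """
    comps = latent.components if isinstance(latent, LatentTrajectory) else np.atleast_2d(latent)
    starts = make_windows(comps.shape[1], spec)
    if bounds is None:
        bounds = compute_bounds(comps)
    maps = density_stack(comps, starts, spec.length_samples, bounds, n_bins, smooth_sd)
    values = _pearson_rows(maps.reshape(len(starts), -1), dtype=corr_dtype)
    return MDFMatrix(
        values=values,
        window_starts=starts,
        window_spec=spec,
        density_params={"n_bins": n_bins, "smooth_sd": smooth_sd},
    )


def _upper(m: MDFMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, MDFMatrix):
        if m.n_windows < 2:
            raise ValueError("need at least 2 windows")
        return m.upper_triangle()
    m = np.asarray(m, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return m[np.triu_indices(m.shape[0], k=1)]


def mdf_std(m: MDFMatrix | np.ndarray, ddof: int = 0) -> float:
    """Population std (ddof=0 by default) of the strict upper triangle.

    This is the scalar complexity statistic: lower values indicate a richer,
    more smoothly explored state repertoire.
    """
    return float(np.std(_upper(m), ddof=ddof))


def mdf_mean(m: MDFMatrix | np.ndarray) -> float:
    """Mean of the strict upper triangle."""
    return float(np.mean(_upper(m)))


def complexity_profile(
    recording: Recording,
    window_lengths_s: np.ndarray | list[float],
    slide_s: float,
    *,
    n_components: int = 2,
    seed: int = 0,
    n_bins: int = 128,
    smooth_sd: float = 8.0,
) -> dict[float, float]:
    """MDF std as a function of window length (seconds).

    The ICA embedding is fitted once per recording; the density/correlation
    stage is repeated for each window length with slide ``slide_s``.
    Returns ``{window_length_s: mdf_std}``.
    """
    latent = fit_ica(recording, n_components=n_components, seed=seed)
    bounds = compute_bounds(latent)
    out: dict[float, float] = {}
    for length_s in window_lengths_s:
        spec = WindowSpec.from_seconds(length_s, slide_s, recording.fs)
        m = mdf_matrix(latent, spec, n_bins=n_bins, smooth_sd=smooth_sd, bounds=bounds)
        out[float(length_s)] = mdf_std(m)
    return out


class ManifoldDensityFlow:
    """Manifold-density-flow model of a multichannel recording.

    Parameters
    ----------
    data : Recording or ndarray, shape (n_channels, n_samples)
        Observed signal; an array requires ``fs``.
    fs : float, optional
        Sampling rate in Hz when ``data`` is a plain array.
    n_components : int
        Latent dimensionality (2 or 3).
    window_length, slide : int, optional
        Window geometry in samples (defaults 800 and 10, the simulation
        benchmark setting).  ``window_length_s``/``slide_s`` express the
        same in seconds and take precedence when given.
    n_bins, smooth_sd : histogram bins per dimension and Gaussian smoothing
        sd in bin units (defaults 128 and 8).
    seed : int
        Seed for the ICA fit.

    Examples
    --------
    >>> model = ManifoldDensityFlow(rec, window_length_s=15.0, slide_s=0.1)
    >>> res = model.fit()
    >>> res.std  # complexity statistic  # doctest: +SKIP
    """

    def __init__(
        self,
        data: Recording | np.ndarray,
        fs: float | None = None,
        *,
        n_components: int = 2,
        window_length: int = 800,
        slide: int = 10,
        window_length_s: float | None = None,
        slide_s: float | None = None,
        n_bins: int = 128,
        smooth_sd: float = 8.0,
        seed: int = 0,
        ica_on_fail: str = "raise",
    ) -> None:
        if isinstance(data, Recording):
            self.recording = data
        else:
            if fs is None:
                raise ValueError("fs is required when data is a plain array")
            self.recording = Recording(data=np.asarray(data, dtype=float), fs=fs)
        if window_length_s is not None:
            window_length = int(round(window_length_s * self.recording.fs))
        if slide_s is not None:
            slide = int(round(slide_s * self.recording.fs))
        self.window_spec = WindowSpec(window_length, slide)
        self.n_components = n_components
        self.n_bins = n_bins
        self.smooth_sd = smooth_sd
        self.seed = seed
        self.ica_on_fail = ica_on_fail

    @classmethod
    def from_recording(cls, recording: Recording, **kwargs) -> "ManifoldDensityFlow":
        return cls(recording, **kwargs)

    def fit(self, latent: LatentTrajectory | None = None) -> "MDFResults":
        """Embed (unless a latent trajectory is supplied) and compute the MDF."""
        if latent is None:
            latent = fit_ica(
                self.recording,
                n_components=self.n_components,
                seed=self.seed,
                on_fail=self.ica_on_fail,
            )
        matrix = mdf_matrix(
            latent, self.window_spec, n_bins=self.n_bins, smooth_sd=self.smooth_sd
        )
        return MDFResults(model=self, latent=latent, matrix=matrix)


class MDFResults:
    """Fitted MDF: latent trajectory, correlation matrix, and statistics."""

    def __init__(
        self, model: ManifoldDensityFlow, latent: LatentTrajectory, matrix: MDFMatrix
    ) -> None:
        self.model = model
        self.latent = latent
        self.matrix = matrix
        self.std = mdf_std(matrix)
        self.mean = mdf_mean(matrix)

    @property
    def n_windows(self) -> int:
        return self.matrix.n_windows

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        rec = self.model.recording
        spec = self.model.window_spec
        lines = [
            "Manifold Density Flow results",
            "=" * 33,
            f"channels:           {rec.n_channels}",
            f"samples:            {rec.n_samples} @ {rec.fs:g} Hz"
            f" ({rec.duration:.1f} s)",
            f"latent components:  {self.latent.n_components}",
            f"window / slide:     {spec.length_samples} / {spec.slide_samples} samples",
            f"bins / smooth sd:   {self.model.n_bins} / {self.model.smooth_sd:g}",
            f"windows:            {self.n_windows}",
            f"MDF mean (upper):   {self.mean:.4f}",
            f"MDF std  (upper):   {self.std:.4f}",
        ]
        return "\n".join(lines)

    def plot_matrix(self, ax=None, **imshow_kw):
        """Heat map of the MDF matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        imshow_kw.setdefault("vmin", -1)
        imshow_kw.setdefault("vmax", 1)
        imshow_kw.setdefault("cmap", "viridis")
        im = ax.imshow(self.matrix.values, origin="lower", **imshow_kw)
        ax.set_xlabel("window")
        ax.set_ylabel("window")
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax

    def plot_latent(self, ax=None, **plot_kw):
        """Latent trajectory in the first two components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.latent.components
        plot_kw.setdefault("lw", 0.3)
        plot_kw.setdefault("alpha", 0.7)
        ax.plot(c[0], c[1], **plot_kw)
        ax.set_xlabel("IC 1")
        ax.set_ylabel("IC 2")
        return ax
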