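"""Multichannel recording container.

A :class:`Recording` is the common currency of the package: a channels x
samples matrix together with its sampling rate, channel labels and an
optional condition label and artifact mask.  Both empirical signals (e.g.
high-frequency activity extracted from intracranial EEG) and synthetic
surrogate recordings are carried in this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """Channels x samples time series with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        The signal. Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str, optional
        Unique channel names; autogenerated ``ch000, ch001, ...`` if omitted.
    condition : str, optional
        Experimental condition label (e.g. ``"rest"``).
    artifact_mask : ndarray of bool, optional
        Same shape as ``data``; True marks samples that were replaced or
        flagged during artifact rejection.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    condition: str | None = None
    artifact_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.n_channels)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.data.shape:
                raise ValueError("artifact_mask shape must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with selected fields replaced."""
        params = dict(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            condition=self.condition,
            artifact_mask=None if self.artifact_mask is None else self.artifact_mask.copy(),
        )
        params.update(kwargs)
        return Recording(**params)
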