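"""Containers for uniformly sampled signals.

A :class:`TimeSeries` is the currency of every operation in this package: a
1-D array of real samples plus its sampling rate. :class:`TwoChannelPPG`
pairs the red and infrared channels of a pulse-oximeter recording, which is
the two-row observation matrix the source-separation step works on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries", "TwoChannelPPG"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like of float
        Signal values, arbitrary units. Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("samples must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must all be finite")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        return self.samples.size

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def rms(self) -> float:
        """Uncorrected root-mean-square (no detrending)."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def standardized(self) -> "TimeSeries":
        """Return a zero-mean, unit-variance copy.

        Raises
        ------
        ValueError
            If the signal has zero variance.
        """
        x = self.samples
        sd = float(np.std(x))
        if sd == 0.0:
            raise ValueError("cannot standardize a zero-variance signal")
        return TimeSeries((x - np.mean(x)) / sd, self.fs)

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return TimeSeries(samples, self.fs)


@dataclass(frozen=True)
class TwoChannelPPG:
    """Paired red / infrared PPG channels of equal length and rate."""

    red: TimeSeries
    ir: TimeSeries

    def __post_init__(self) -> None:
        if len(self.red) != len(self.ir):
            raise ValueError(
                f"channel length mismatch: red {len(self.red)}, ir {len(self.ir)}"
            )
        if self.red.fs != self.ir.fs:
            raise ValueError(
                f"channel rate mismatch: red {self.red.fs} Hz, ir {self.ir.fs} Hz"
            )

    @property
    def fs(self) -> float:
        return self.red.fs

    @property
    def n(self) -> int:
        return len(self.red)

    def as_matrix(self) -> np.ndarray:
        """Observation matrix, shape (2, n): row 0 red, row 1 ir."""
        return np.vstack([self.red.samples, self.ir.samples])
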