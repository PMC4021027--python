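"""Comparison methods: spectral-subtraction LMS and moving-average filter.

The FFT-LMS scheme builds a motion-artifact reference by zeroing the
pulsatile (0.5–4 Hz) and respiratory (0.2–0.35 Hz) bands of the corrupted
record's spectrum and inverse-transforming; what remains is fed to the LMS
filter as a *noise-correlated* reference, so there the cleaned signal is
the error output — the opposite role assignment from the amplitude-recovery
step, whose reference is signal-correlated.

The moving-average filter simply smooths the corrupted record with a
centered box window; it suppresses sporadic high-frequency noise but cannot
touch in-band artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lms import LmsParams, LmsResult, lms_multipass
from .timeseries import TimeSeries

__all__ = ["FftLmsBands", "synthesize_ma_reference", "fft_lms", "maf"]


@dataclass(frozen=True)
class FftLmsBands:
    """Spectral bands zeroed when synthesizing the artifact reference."""

    pulsatile_hz: tuple[float, float] = (0.5, 4.0)
    respiratory_hz: tuple[float, float] = (0.2, 0.35)

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in (("pulsatile_hz", self.pulsatile_hz),
                               ("respiratory_hz", self.respiratory_hz)):
            if not (0 < lo < hi < fs / 2):
                raise ValueError(f"{name}={lo, hi} must lie inside (0, {fs / 2})")


def synthesize_ma_reference(x: TimeSeries, bands: FftLmsBands | None = None) -> TimeSeries:
    """Artifact reference by zeroing pulse and respiration spectral bands.

    A single full-record DFT; bins whose frequency falls inside either band
    (edges inclusive, negative frequencies mirrored) are set to zero, then
    the inverse transform is taken. The result is real by construction.
    """
    bands = bands or FftLmsBands()
    bands.validate(x.fs)
    n = len(x)
    spec = np.fft.rfft(x.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / x.fs)
    mask = np.zeros(freqs.shape, dtype=bool)
    for lo, hi in (bands.pulsatile_hz, bands.respiratory_hz):
        mask |= (freqs >= lo) & (freqs <= hi)
    spec[mask] = 0.0
    return x.with_samples(np.fft.irfft(spec, n))


def fft_lms(
    x: TimeSeries,
    bands: FftLmsBands | None = None,
    params: LmsParams | None = None,
    n_passes: int = 1,
    return_result: bool = False,
) -> TimeSeries | tuple[TimeSeries, LmsResult]:
    """Denoise by LMS against the synthesized artifact reference.

    The reference is noise-correlated, so the cleaned record is the LMS
    *error* ``e = x - y``; ``y`` is the cancelled artifact estimate.
    """
    ref = synthesize_ma_reference(x, bands)
    res = lms_multipass(ref, x, params, n_passes)
    recovered = res.e
    return (recovered, res) if return_result else recovered


def maf(x: TimeSeries, window_s: float = 0.1) -> TimeSeries:
    """Centered moving average with an odd box window.

    The window length is ``round(window_s * fs)`` forced odd; edges are
    handled by shrinking the window, so constants pass through unchanged
    and the output stays within [min(x), max(x)].
    """
    w = int(round(window_s * x.fs))
    if w < 1 or w >= len(x):
        raise ValueError(
            f"window of {window_s} s -> {w} samples is outside (0, {len(x)})"
        )
    if w % 2 == 0:
        w += 1
    if w >= len(x):
        raise ValueError("window too long after rounding to odd length")
    h = w // 2
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x.samples)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return x.with_samples(out)
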