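"""Conditioning of raw PPG records before source separation.

Four steps: FIR low-pass design for high-frequency noise (Hamming window,
at least 20 dB down at 8 Hz by default), first-order IIR baseline (DC)
removal ``H(z) = (1 - z^-1) / (1 - 0.992 z^-1)``, autocorrelation pulse-
period estimation within the physiological band, and generation of the
rectangular-pulse reference train that anchors the constrained ICA step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "FilterSpec",
    "PeriodEstimate",
    "design_lowpass",
    "apply_lowpass",
    "remove_dc",
    "estimate_period",
    "make_reference",
]

DEFAULT_DC_POLE = 0.992


@dataclass(frozen=True)
class FilterSpec:
    """A designed FIR low-pass: edges, attenuation requirement, and taps."""

    fs: float
    passband_edge_hz: float
    stopband_edge_hz: float
    min_stop_atten_db: float
    taps: np.ndarray

    def magnitude_db(self, freq_hz: float) -> float:
        """Single-frequency magnitude response in dB relative to unity."""
        _, h = sps.freqz(self.taps, worN=[freq_hz], fs=self.fs)
        return float(20 * np.log10(np.abs(h[0]) + 1e-300))


@dataclass(frozen=True)
class PeriodEstimate:
    """Pulse period from the autocorrelation peak, sub-sample interpolated."""

    period_samples: float
    period_s: float
    peak_lag_correlation: float
    search_range_samples: tuple[int, int]


def design_lowpass(
    fs: float,
    passband_edge_hz: float = 4.0,
    stopband_edge_hz: float = 8.0,
    min_stop_atten_db: float = 20.0,
) -> FilterSpec:
    """Design a linear-phase Hamming-window FIR low-pass.

    The tap count follows the window-method length estimate for the
    requested transition width, then is grown if the verified response at
    the stopband edge misses ``min_stop_atten_db``. DC gain is unity.
    """
    if not (0 < passband_edge_hz < stopband_edge_hz < fs / 2):
        raise ValueError(
            f"need 0 < passband ({passband_edge_hz}) < stopband "
            f"({stopband_edge_hz}) < Nyquist ({fs / 2})"
        )
    if min_stop_atten_db <= 0:
        raise ValueError("min_stop_atten_db must be positive")
    width = stopband_edge_hz - passband_edge_hz
    cutoff = 0.5 * (passband_edge_hz + stopband_edge_hz)
    # Hamming main-lobe transition-width estimate: df ~ 3.3 / N (normalized)
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd -> type-I linear phase
    for _ in range(8):
        taps = sps.firwin(numtaps, cutoff, window="hamming", fs=fs)
        spec = FilterSpec(fs, passband_edge_hz, stopband_edge_hz,
                          min_stop_atten_db, taps)
        if spec.magnitude_db(stopband_edge_hz) <= -min_stop_atten_db:
            return spec
        numtaps = int(numtaps * 1.5) | 1
    raise RuntimeError("FIR design failed to meet the stopband specification")


def apply_lowpass(spec: FilterSpec, x: TimeSeries) -> TimeSeries:
    """Apply the FIR zero-phase (forward-backward), preserving timing."""
    padlen = min(3 * len(spec.taps), len(x) - 1)
    y = sps.filtfilt(spec.taps, [1.0], x.samples, padlen=padlen)
    return x.with_samples(y)


def remove_dc(x: TimeSeries, pole: float = DEFAULT_DC_POLE,
              zero_phase: bool = False) -> TimeSeries:
    """Remove the baseline with ``H(z) = (1 - z^-1) / (1 - pole z^-1)``.

    By default implements the recursion
    ``y[n] = x[n] - x[n-1] + pole * y[n-1]`` with zero initial conditions.
    The transfer function has an exact zero at DC, so a constant input
    decays to zero. With ``zero_phase`` the same filter is applied
    forward-backward, removing its phase shift near the pulse fundamental
    (at the price of squaring the magnitude response); the denoising
    pipeline uses this form so waveform timing — and hence per-cycle
    amplitude readings — is preserved.
    """
    if not (0 < pole < 1):
        raise ValueError("pole must lie in (0, 1)")
    if zero_phase:
        # the near-DC pole has a ~1/(1-pole)-sample transient; scipy's
        # default padding is far too short for it
        padlen = min(len(x) - 1, int(np.ceil(6.0 / (1.0 - pole))))
        y = sps.filtfilt([1.0, -1.0], [1.0, -pole], x.samples, padlen=padlen)
    else:
        y = sps.lfilter([1.0, -1.0], [1.0, -pole], x.samples)
    return x.with_samples(y)


def estimate_period(
    x: TimeSeries, min_hz: float = 0.5, max_hz: float = 4.0,
    tie_tol: float = 0.1,
) -> PeriodEstimate:
    """Estimate the pulse period from the autocorrelation peak.

    The biased, zero-mean autocorrelation is searched over lags mapping to
    [min_hz, max_hz]. Among the local maxima whose height is within
    ``tie_tol`` (relative) of the tallest one, the shortest lag wins: a
    quasi-periodic pulse repeats at every multiple of its period, so the
    sub-harmonic peaks at 2T, 3T, ... are near-ties of the fundamental and
    must not capture the estimate. The winning integer lag is refined by
    parabolic interpolation for sub-sample precision.
    """
    if not (0 < min_hz < max_hz):
        raise ValueError("need 0 < min_hz < max_hz")
    if not (0 <= tie_tol < 1):
        raise ValueError("tie_tol must lie in [0, 1)")
    n = len(x)
    if x.duration_s < 3.0 / min_hz:
        raise ValueError(
            f"record too short: need >= {3.0 / min_hz:.1f} s at min_hz={min_hz}"
        )
    samples = x.samples - np.mean(x.samples)
    if np.all(samples == 0):
        raise ValueError("all-zero signal: period undefined")
    # biased autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(samples, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    lo = int(np.ceil(x.fs / max_hz))
    hi = int(np.floor(x.fs / min_hz))
    hi = min(hi, n - 2)
    if lo >= hi:
        raise ValueError("search range empty for this record length / band")
    seg = acf[lo:hi + 1]
    best = float(seg.max())
    # local maxima of the full autocorrelation (so a peak sitting exactly on
    # the search-range edge is still seen), restricted to the lag range
    peaks = sps.argrelmax(acf[:hi + 2])[0]
    candidates = [int(p) for p in peaks
                  if lo <= p <= hi and acf[p] >= best - tie_tol * abs(best)]
    k = min(candidates) if candidates else lo + int(np.argmax(seg))
    # parabolic refinement around the integer peak
    if lo < k < hi:
        a, b, c = acf[k - 1], acf[k], acf[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    period = k + delta
    corr = float(np.clip(acf[k] / acf[0], -1.0, 1.0))
    return PeriodEstimate(
        period_samples=float(period),
        period_s=float(period / x.fs),
        peak_lag_correlation=corr,
        search_range_samples=(lo, hi),
    )


def make_reference(
    period_samples: float,
    n_samples: int,
    duty: float = 0.2,
    fs: float = 1.0,
    offset_samples: float = 0.0,
) -> TimeSeries:
    """Build the standardized rectangular-pulse reference train.

    One pulse of width ``round(duty * period)`` samples per cycle, onsets
    at ``offset + k * period`` (period may be fractional); output is
    zero-mean, unit-variance.
    """
    if not (1 < period_samples < n_samples):
        raise ValueError(
            f"period_samples must lie in (1, n_samples), got {period_samples}"
        )
    if not (0 < duty < 1):
        raise ValueError("duty must lie in (0, 1)")
    width = max(1, int(round(duty * period_samples)))
    ref = np.zeros(n_samples)
    offset = float(offset_samples) % float(period_samples)
    k = 0
    while True:
        onset = int(round(offset + k * period_samples))
        if onset >= n_samples:
            break
        ref[onset:onset + width] = 1.0
        k += 1
    ref -= ref.mean()
    sd = ref.std()
    if sd == 0:
        raise ValueError("degenerate reference (constant); check duty/period")
    return TimeSeries(ref / sd, fs)


def align_reference(
    x: TimeSeries,
    period_samples: float,
    duty: float = 0.2,
) -> TimeSeries:
    """Reference train phase-aligned to a signal sharing its period.

    The correlation-based closeness that anchors the constrained
    extraction compares signals at lag zero, so the pulse train must sit
    on the signal's own beat phase to be informative. The onset offset is
    chosen by circular cross-correlation of the signal with a zero-offset
    train, scanning one full period.
    """
    n = len(x)
    xs = x.samples - x.samples.mean()
    # scan every integer onset offset over one period; the |correlation|
    # is what matters — a train locked onto the troughs is as informative
    # as one on the peaks under the sign-folded closeness
    best_ref = None
    best_score = -1.0
    for o in range(int(np.ceil(period_samples))):
        ref = make_reference(period_samples, n, duty=duty, fs=x.fs,
                             offset_samples=o)
        score = abs(float(np.dot(ref.samples, xs)))
        if score > best_score:
            best_score = score
            best_ref = ref
    return best_ref
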