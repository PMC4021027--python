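"""Synthetic two-channel PPG records, motion artifacts, and scoring.

The generator stands in for recorded data: a quasi-periodic pulse waveform
shared by the red and infrared channels, an additive artifact waveform, a
mixer that scales the artifact to hit a requested signal-to-noise ratio

.. math:: x(t) = s(t) + \\lambda\\,\\mathrm{MA}(t), \\qquad
          \\mathrm{SNR} = 20\\log_{10}\\frac{\\mathrm{RMS}(s)}
          {\\mathrm{RMS}(\\lambda\\,\\mathrm{MA})}\\ \\mathrm{dB},

and the relative RMS error used to score a reconstruction,
``RRMSE = 100 * RMS(s - s_hat) / RMS(s)`` (percent).

The clean-pulse model is a sum of decaying sinusoid harmonics plus a
delayed, attenuated copy acting as a dicrotic-wave surrogate; cycle-to-cycle
period jitter makes it quasi-periodic rather than strictly periodic. The
red and infrared channels carry the same waveform at different amplitudes,
plus a small independent sensor-noise floor per channel that keeps
artifact-free records full-rank for whitening.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries, TwoChannelPPG

__all__ = [
    "PpgModelParams",
    "ArtifactModelParams",
    "MixtureResult",
    "generate_clean_ppg",
    "generate_artifact",
    "mix_at_snr",
    "mix_two_channel",
    "rrmse",
]

_PPG_BAND_HZ = (0.5, 4.0)  # physiological pulse band
_ARTIFACT_MODELS = ("band_noise", "random_walk", "transient_bumps", "composite")

# Dicrotic-wave amplitude relative to the main pulse (same in both
# channels: the two wavelengths see the same pulse waveform, scaled).
_DICROTIC_AMP = 0.45


@dataclass(frozen=True)
class PpgModelParams:
    """Parameters of the quasi-periodic clean-pulse generator.

    heart_rate_hz must lie in the physiological pulse band [0.5, 4] Hz.
    ``red_ir_amplitude_ratio`` fixes RMS(red)/RMS(ir) exactly.
    """

    heart_rate_hz: float = 1.25
    duration_s: float = 20.0
    fs: float = 200.0
    n_harmonics: int = 4
    harmonic_decay: float = 0.5
    dicrotic_delay_frac: float = 0.35
    hr_jitter_frac: float = 0.02
    red_ir_amplitude_ratio: float = 0.6
    sensor_noise_frac: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not (_PPG_BAND_HZ[0] <= self.heart_rate_hz <= _PPG_BAND_HZ[1]):
            raise ValueError(
                f"heart_rate_hz must be in [{_PPG_BAND_HZ[0]}, {_PPG_BAND_HZ[1]}] Hz, "
                f"got {self.heart_rate_hz}"
            )
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (0 < self.harmonic_decay < 1):
            raise ValueError("harmonic_decay must lie in (0, 1)")
        if not (0 < self.dicrotic_delay_frac < 1):
            raise ValueError("dicrotic_delay_frac must lie in (0, 1)")
        if self.hr_jitter_frac < 0:
            raise ValueError("hr_jitter_frac must be >= 0")
        if self.red_ir_amplitude_ratio <= 0:
            raise ValueError("red_ir_amplitude_ratio must be positive")
        if self.sensor_noise_frac < 0:
            raise ValueError("sensor_noise_frac must be >= 0")


@dataclass(frozen=True)
class ArtifactModelParams:
    """Parameters of the surrogate motion-artifact generator.

    ``band_hz`` is the shaping band for ``band_noise``; every model produces
    spectral energy overlapping the pulse band (0.5–4 Hz), which is the
    regime where fixed-cutoff filtering fails. ``bump_rate_hz`` and
    ``bump_width_s`` only affect ``transient_bumps`` / ``composite``.
    """

    model: str = "band_noise"
    band_hz: tuple[float, float] = (0.1, 4.0)
    duration_s: float = 20.0
    fs: float = 200.0
    bump_rate_hz: float = 0.5
    bump_width_s: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.model not in _ARTIFACT_MODELS:
            raise ValueError(f"model must be one of {_ARTIFACT_MODELS}, got {self.model!r}")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        lo, hi = self.band_hz
        if not (0 <= lo < hi):
            raise ValueError(f"band_hz must be a nonempty interval, got {self.band_hz}")
        if hi > self.fs / 2:
            raise ValueError(f"band_hz upper edge {hi} Hz exceeds Nyquist {self.fs / 2} Hz")
        if self.bump_rate_hz < 0 or self.bump_width_s <= 0:
            raise ValueError("bump_rate_hz must be >= 0 and bump_width_s > 0")


@dataclass(frozen=True)
class MixtureResult:
    """An artifact-corrupted signal with its mixing scale and achieved SNR."""

    x: TimeSeries
    lam: float
    snr_db: float


def _cycle_waveform(phase: np.ndarray, n_harmonics: int, decay: float,
                    dicrotic_delay_frac: float, dicrotic_amp: float) -> np.ndarray:
    """Evaluate the pulse waveform at (fractional) cycle phase values."""
    def harmonics(p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        for m in range(1, n_harmonics + 1):
            out += decay ** (m - 1) * np.sin(2 * np.pi * m * p)
        return out

    return harmonics(phase) + dicrotic_amp * harmonics(phase - dicrotic_delay_frac)


def _jittered_phase(params: PpgModelParams, rng: np.random.Generator) -> np.ndarray:
    """Cycle phase at each sample time under cycle-to-cycle period jitter."""
    t = np.arange(round(params.duration_s * params.fs)) / params.fs
    base_period = 1.0 / params.heart_rate_hz
    n_cycles = int(np.ceil(params.duration_s / base_period * 1.5)) + 3
    eps = np.clip(rng.standard_normal(n_cycles), -2.5, 2.5)
    periods = base_period * (1.0 + params.hr_jitter_frac * eps)
    periods = np.maximum(periods, 0.2 * base_period)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.searchsorted(starts, t, side="right") - 1
    return idx + (t - starts[idx]) / periods[idx]


def generate_clean_ppg(params: PpgModelParams) -> TwoChannelPPG:
    """Generate a clean two-channel pulse record.

    Both channels carry the same pulse waveform (shared cycle timing and
    morphology) plus independent additive sensor noise at
    ``sensor_noise_frac`` of the waveform's RMS — without that noise floor
    the two channels would be exactly collinear and artifact-free records
    could not be whitened. Channels are normalised so that
    ``RMS(red) / RMS(ir) == red_ir_amplitude_ratio`` exactly, and each is
    zero-mean. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    phase = _jittered_phase(params, rng)

    wave = _cycle_waveform(phase, params.n_harmonics, params.harmonic_decay,
                           params.dicrotic_delay_frac, _DICROTIC_AMP)
    wave -= wave.mean()
    sigma = params.sensor_noise_frac * np.sqrt(np.mean(wave**2))
    ir = wave + sigma * rng.standard_normal(wave.size)
    red = wave + sigma * rng.standard_normal(wave.size)
    ir -= ir.mean()
    red -= red.mean()
    # exact RMS ratio between channels
    red *= (params.red_ir_amplitude_ratio
            * np.sqrt(np.mean(ir**2)) / np.sqrt(np.mean(red**2)))
    return TwoChannelPPG(
        red=TimeSeries(red, params.fs), ir=TimeSeries(ir, params.fs)
    )


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[~((freqs >= band[0]) & (freqs <= band[1]))] = 0.0
    return np.fft.irfft(spec, n)


def _random_walk(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    walk = np.cumsum(rng.standard_normal(n))
    t = np.arange(n)
    # remove linear trend so the drift stays bounded and zero-mean
    coeffs = np.polyfit(t, walk, 1)
    return walk - np.polyval(coeffs, t)


def _transient_bumps(n: int, fs: float, rate_hz: float, width_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    expected = rate_hz * n / fs
    n_bumps = rng.poisson(expected) if expected > 0 else 0
    width = width_s * fs
    t = np.arange(n)
    for _ in range(n_bumps):
        center = rng.uniform(0, n)
        amp = rng.normal(0.0, 1.0)
        out += amp * np.exp(-0.5 * ((t - center) / (width / 2)) ** 2)
    return out


def generate_artifact(params: ArtifactModelParams) -> TimeSeries:
    """Generate a zero-mean surrogate motion-artifact waveform.

    Models: band-limited Gaussian noise (spectral shaping), detrended random
    walk, randomly timed smooth bumps, or an equal-weight composite of the
    three. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = round(params.duration_s * params.fs)

    if params.model == "band_noise":
        x = _band_noise(n, params.fs, params.band_hz, rng)
    elif params.model == "random_walk":
        x = _random_walk(n, params.fs, rng)
    elif params.model == "transient_bumps":
        x = _transient_bumps(n, params.fs, params.bump_rate_hz,
                             params.bump_width_s, rng)
    else:  # composite
        parts = [
            _band_noise(n, params.fs, params.band_hz, rng),
            _random_walk(n, params.fs, rng),
            _transient_bumps(n, params.fs, params.bump_rate_hz,
                             params.bump_width_s, rng),
        ]
        x = np.zeros(n)
        for p in parts:
            sd = p.std()
            if sd > 0:
                x += p / sd
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms
    return TimeSeries(x, params.fs)


def mix_at_snr(s: TimeSeries, ma: TimeSeries, snr_db: float) -> MixtureResult:
    """Mix artifact into a clean signal at a requested SNR.

    The scale is the closed form
    ``lam = RMS(s) / (RMS(ma) * 10**(snr_db / 20))`` so that the achieved
    SNR equals ``snr_db`` exactly; the mixture is ``x = s + lam * ma``.
    """
    if len(s) != len(ma) or s.fs != ma.fs:
        raise ValueError("s and ma must share length and sampling rate")
    rms_s, rms_ma = s.rms(), ma.rms()
    if rms_s == 0 or rms_ma == 0:
        raise ValueError("zero-RMS input: cannot define an SNR")
    lam = rms_s / (rms_ma * 10.0 ** (snr_db / 20.0))
    x = TimeSeries(s.samples + lam * ma.samples, s.fs)
    return MixtureResult(x=x, lam=float(lam), snr_db=float(snr_db))


def mix_two_channel(
    ppg: TwoChannelPPG, ma: TimeSeries, snr_db: float,
    reference_channel: str = "ir",
) -> tuple[TwoChannelPPG, float, dict[str, float]]:
    """Mix one artifact waveform into both channels with a single scale.

    The scale λ is chosen so the *reference channel* (default infrared,
    the channel the period estimate uses) sits at ``snr_db``; the same
    λ·MA is added to both channels, as when one physical disturbance
    couples into both optical paths. A shared λ keeps the two-source
    mixing matrix invertible — scaling the artifact per channel to
    equalise SNR would make the artifact column proportional to the pulse
    column and no linear unmixing could separate them.

    Returns the mixed record, λ, and the achieved per-channel SNRs in dB.
    """
    if reference_channel not in ("red", "ir"):
        raise ValueError("reference_channel must be 'red' or 'ir'")
    ref = ppg.ir if reference_channel == "ir" else ppg.red
    lam = mix_at_snr(ref, ma, snr_db).lam
    scaled = TimeSeries(lam * ma.samples, ma.fs)
    mixed = TwoChannelPPG(
        red=TimeSeries(ppg.red.samples + scaled.samples, ppg.fs),
        ir=TimeSeries(ppg.ir.samples + scaled.samples, ppg.fs),
    )
    snrs = {"red": achieved_snr_db(ppg.red, scaled),
            "ir": achieved_snr_db(ppg.ir, scaled)}
    return mixed, float(lam), snrs


def achieved_snr_db(s: TimeSeries, scaled_ma: TimeSeries) -> float:
    """SNR in dB of a clean signal against an (already scaled) artifact."""
    return 20.0 * np.log10(s.rms() / scaled_ma.rms())


def rrmse(s: TimeSeries, s_hat: TimeSeries) -> float:
    """Relative root-mean-square error of a reconstruction, in percent."""
    if len(s) != len(s_hat):
        raise ValueError("signals must have equal length")
    rms_s = s.rms()
    if rms_s == 0:
        raise ValueError("reference signal has zero RMS")
    err = np.sqrt(np.mean((s.samples - s_hat.samples) ** 2))
    return float(100.0 * err / rms_s)
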