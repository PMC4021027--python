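"""Generators, SNR-controlled mixing, and the RRMSE score."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from ppgclean import (ArtifactModelParams, PpgModelParams, TimeSeries,
                      achieved_snr_db, generate_artifact, generate_clean_ppg,
                      mix_at_snr, mix_two_channel, rrmse)


def autocorr_peak_lag(x: np.ndarray, lo: int, hi: int) -> int:
    """Oracle: exhaustive full-autocorrelation search over a lag range."""
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[len(x) - 1:]
    return lo + int(np.argmax(full[lo:hi + 1]))


class TestCleanPpg:
    @pytest.mark.parametrize("duration_s,fs", [(20.0, 200.0), (10.0, 100.0)])
    def test_length_is_duration_times_rate(self, duration_s, fs):
        ppg = generate_clean_ppg(PpgModelParams(duration_s=duration_s, fs=fs))
        assert ppg.n == round(duration_s * fs)

    def test_channels_zero_mean(self, clean_ppg):
        assert abs(clean_ppg.red.samples.mean()) < 1e-12
        assert abs(clean_ppg.ir.samples.mean()) < 1e-12

    @pytest.mark.parametrize("ratio", [0.3, 0.6, 1.7])
    def test_rms_ratio_exact(self, ratio):
        ppg = generate_clean_ppg(PpgModelParams(red_ir_amplitude_ratio=ratio))
        assert ppg.red.rms() / ppg.ir.rms() == pytest.approx(ratio, abs=1e-12)

    def test_period_matches_heart_rate(self):
        # no jitter: the autocorrelation oracle must find fs/hr exactly
        ppg = generate_clean_ppg(PpgModelParams(
            heart_rate_hz=1.25, fs=200.0, hr_jitter_frac=0.0,
            sensor_noise_frac=0.0))
        lag = autocorr_peak_lag(ppg.ir.samples, 50, 400)
        assert abs(lag - 160) <= 1

    def test_deterministic_given_seed(self):
        a = generate_clean_ppg(PpgModelParams(seed=3))
        b = generate_clean_ppg(PpgModelParams(seed=3))
        c = generate_clean_ppg(PpgModelParams(seed=4))
        np.testing.assert_array_equal(a.ir.samples, b.ir.samples)
        assert not np.array_equal(a.ir.samples, c.ir.samples)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_clean_ppg(PpgModelParams(heart_rate_hz=5.0)).red
        with pytest.raises(ValueError):
            generate_clean_ppg(PpgModelParams(harmonic_decay=1.5)).red
        with pytest.raises(ValueError):
            generate_clean_ppg(PpgModelParams(duration_s=-1.0)).red


class TestArtifact:
    def test_band_noise_energy_concentrated_in_band(self):
        params = ArtifactModelParams(model="band_noise", band_hz=(0.1, 4.0),
                                     fs=200.0, duration_s=20.0, seed=5)
        art = generate_artifact(params)
        freqs, pxx = sps.periodogram(art.samples, fs=art.fs)
        in_band = (freqs >= 0.1) & (freqs <= 4.0)
        assert pxx[in_band].sum() / pxx.sum() >= 0.5

    @pytest.mark.parametrize("model", ["band_noise", "random_walk",
                                       "transient_bumps", "composite"])
    def test_zero_mean_and_deterministic(self, model):
        p = ArtifactModelParams(model=model, seed=9)
        a = generate_artifact(p)
        b = generate_artifact(p)
        assert abs(a.samples.mean()) < 1e-9
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_bump_rate_gives_silence(self):
        art = generate_artifact(ArtifactModelParams(
            model="transient_bumps", bump_rate_hz=0.0))
        assert np.all(art.samples == 0.0)

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            generate_artifact(ArtifactModelParams(band_hz=(2.0, 2.0)))
        with pytest.raises(ValueError):
            generate_artifact(ArtifactModelParams(band_hz=(0.1, 150.0), fs=200.0))


class TestMixing:
    def test_equal_rms_zero_db_gives_unit_lambda(self):
        s = TimeSeries(np.tile([1.0, -1.0], 100), 200.0)
        ma = TimeSeries(np.tile([-1.0, 1.0], 100), 200.0)
        res = mix_at_snr(s, ma, 0.0)
        assert res.lam == pytest.approx(1.0)

    def test_closed_form_lambda(self):
        # RMS(s) = 2, RMS(ma) = 1, 20 dB -> lam = 2 / (1 * 10) = 0.2
        s = TimeSeries(np.tile([2.0, -2.0], 100), 200.0)
        ma = TimeSeries(np.tile([1.0, -1.0], 100), 200.0)
        res = mix_at_snr(s, ma, 20.0)
        assert res.lam == pytest.approx(0.2)
        scaled = TimeSeries(res.lam * ma.samples, 200.0)
        assert achieved_snr_db(s, scaled) == pytest.approx(20.0, abs=1e-9)

    def test_mixture_identity(self, clean_ppg, artifact):
        res = mix_at_snr(clean_ppg.ir, artifact, -5.0)
        np.testing.assert_allclose(
            res.x.samples,
            clean_ppg.ir.samples + res.lam * artifact.samples, rtol=0,
            atol=1e-15)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(snr_db=st.floats(-30, 30), seed=st.integers(0, 10_000))
    def test_snr_round_trip(self, snr_db, seed):
        """Re-evaluating the SNR definition on the mix returns the request."""
        rng = np.random.default_rng(seed)
        s = TimeSeries(rng.standard_normal(500) + 0.1, 100.0)
        ma = TimeSeries(rng.standard_normal(500), 100.0)
        res = mix_at_snr(s, ma, snr_db)
        scaled = TimeSeries(res.lam * ma.samples, 100.0)
        assert achieved_snr_db(s, scaled) == pytest.approx(snr_db, abs=1e-9)

    def test_zero_rms_inputs_rejected(self):
        z = TimeSeries(np.zeros(100), 100.0)
        s = TimeSeries(np.ones(100), 100.0)
        with pytest.raises(ValueError):
            mix_at_snr(z, s, 0.0)
        with pytest.raises(ValueError):
            mix_at_snr(s, z, 0.0)

    def test_two_channel_mixing_shares_lambda(self, clean_ppg, artifact):
        mixed, lam, snrs = mix_two_channel(clean_ppg, artifact, 0.0)
        assert snrs["ir"] == pytest.approx(0.0, abs=1e-9)
        # the same scaled artifact is added to both channels
        np.testing.assert_allclose(
            mixed.red.samples - clean_ppg.red.samples,
            mixed.ir.samples - clean_ppg.ir.samples, rtol=0, atol=1e-12)
        # red channel SNR shifted by its amplitude ratio
        assert snrs["red"] == pytest.approx(20 * np.log10(0.6), abs=1e-9)


class TestRrmse:
    def test_identity_zeros_and_double(self, clean_ppg):
        s = clean_ppg.ir
        assert rrmse(s, s) == pytest.approx(0.0)
        zeros = TimeSeries(np.zeros(len(s)), s.fs)
        assert rrmse(s, zeros) == pytest.approx(100.0)
        double = TimeSeries(2 * s.samples, s.fs)
        assert rrmse(s, double) == pytest.approx(100.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(-3, 3))
    def test_scale_reporting(self, a):
        """rrmse(s, a*s) = 100*|1-a|: the score reports scale errors."""
        rng = np.random.default_rng(0)
        s = TimeSeries(rng.standard_normal(256), 100.0)
        scaled = TimeSeries(a * s.samples, 100.0)
        assert rrmse(s, scaled) == pytest.approx(100 * abs(1 - a), abs=1e-9)

    def test_errors(self):
        s = TimeSeries(np.ones(10), 10.0)
        with pytest.raises(ValueError):
            rrmse(s, TimeSeries(np.ones(9), 10.0))
        with pytest.raises(ValueError):
            rrmse(TimeSeries(np.zeros(10), 10.0), s)
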