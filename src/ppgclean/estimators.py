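"""scikit-learn-style denoising transformers.

Records are arrays of shape ``(n_samples, 2)`` with columns (red, ir) and
rows in time order. ``fit`` learns record-level state (the pulse period,
the reference train, the constrained-ICA unmixing direction); ``transform``
applies preprocessing, component extraction with the fitted direction, and
per-channel LMS amplitude recovery to the given record. For the usual
single-record workflow ``fit_transform(X)`` denoises ``X`` itself.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import baselines
from .cica import CicaParams, extract_component, whiten
from .config import PipelineConfig
from .lms import LmsParams, recover_amplitude
from .preprocess import (align_reference, apply_lowpass, design_lowpass,
                         estimate_period, remove_dc)
from .timeseries import TimeSeries, TwoChannelPPG

__all__ = ["CicaLmsDenoiser", "FftLmsDenoiser", "MovingAverageDenoiser"]


def _as_ppg(X: np.ndarray, fs: float) -> TwoChannelPPG:
    X = check_array(X, ensure_min_samples=10)
    if X.shape[1] != 2:
        raise ValueError(f"expected 2 columns (red, ir), got {X.shape[1]}")
    return TwoChannelPPG(red=TimeSeries(X[:, 0], fs), ir=TimeSeries(X[:, 1], fs))


class _PreprocMixin:
    def _preprocess(self, ppg: TwoChannelPPG) -> TwoChannelPPG:
        spec = design_lowpass(self.fs, self.lowpass_pass_hz,
                              self.lowpass_stop_hz, self.lowpass_min_atten_db)
        red = remove_dc(apply_lowpass(spec, ppg.red), self.dc_pole,
                        zero_phase=True)
        ir = remove_dc(apply_lowpass(spec, ppg.ir), self.dc_pole,
                       zero_phase=True)
        return TwoChannelPPG(red=red, ir=ir)


class CicaLmsDenoiser(TransformerMixin, BaseEstimator, _PreprocMixin):
    """Two-channel PPG denoiser: constrained ICA plus LMS amplitude recovery.

    Parameters mirror the pipeline configuration; fitted attributes carry
    the record-level estimates.

    Attributes
    ----------
    period_ : float
        Estimated pulse period in samples (from the IR channel).
    w_ : ndarray of shape (2,)
        Constrained-ICA weight vector in the whitened space.
    whitening_matrix_ : ndarray of shape (2, 2)
    mean_ : ndarray of shape (2,)
    cica_result_ : CicaResult
    """

    def __init__(self, fs: float = 200.0, lowpass_pass_hz: float = 4.0,
                 lowpass_stop_hz: float = 8.0, lowpass_min_atten_db: float = 20.0,
                 dc_pole: float = 0.992, period_min_hz: float = 0.5,
                 period_max_hz: float = 4.0, reference_duty: float = 0.2,
                 contrast: str = "logcosh", rho: float = 1.0,
                 xi: float | None = None, max_iter: int = 500,
                 tol: float = 1e-7, penalty_init: float = 10.0,
                 lms_order: int = 16, lms_mu: float = 0.001,
                 lms_normalize_mu: bool = True, lms_passes: int = 3):
        self.fs = fs
        self.lowpass_pass_hz = lowpass_pass_hz
        self.lowpass_stop_hz = lowpass_stop_hz
        self.lowpass_min_atten_db = lowpass_min_atten_db
        self.dc_pole = dc_pole
        self.period_min_hz = period_min_hz
        self.period_max_hz = period_max_hz
        self.reference_duty = reference_duty
        self.contrast = contrast
        self.rho = rho
        self.xi = xi
        self.max_iter = max_iter
        self.tol = tol
        self.penalty_init = penalty_init
        self.lms_order = lms_order
        self.lms_mu = lms_mu
        self.lms_normalize_mu = lms_normalize_mu
        self.lms_passes = lms_passes

    def fit(self, X, y=None):
        ppg = _as_ppg(X, self.fs)
        pre = self._preprocess(ppg)
        est = estimate_period(pre.ir, self.period_min_hz, self.period_max_hz)
        ref = align_reference(pre.ir, est.period_samples,
                              duty=self.reference_duty)
        res = extract_component(pre, ref, CicaParams(
            rho=self.rho, xi=self.xi, contrast=self.contrast,
            max_iter=self.max_iter, tol=self.tol,
            penalty_init=self.penalty_init))
        wd = whiten(pre)
        self.period_ = est.period_samples
        self.period_estimate_ = est
        self.reference_ = ref
        self.cica_result_ = res
        self.w_ = res.w
        self.whitening_matrix_ = wd.whitening_matrix
        self.mean_ = wd.mean_vector
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "w_")
        ppg = _as_ppg(X, self.fs)
        pre = self._preprocess(ppg)
        unmix = self.w_ @ self.whitening_matrix_
        comp = unmix @ (pre.as_matrix() - self.mean_[:, None])
        sd = comp.std()
        if sd == 0:
            raise ValueError("extracted component is constant")
        comp = TimeSeries((comp - comp.mean()) / sd, self.fs)
        lp = LmsParams(order=self.lms_order, mu=self.lms_mu,
                       normalize_mu=self.lms_normalize_mu)
        rec_red, _ = recover_amplitude(pre.red, comp, lp, self.lms_passes)
        rec_ir, _ = recover_amplitude(pre.ir, comp, lp, self.lms_passes)
        return np.column_stack([rec_red.samples, rec_ir.samples])


class FftLmsDenoiser(TransformerMixin, BaseEstimator, _PreprocMixin):
    """Per-channel spectral-subtraction LMS baseline as a transformer.

    Stateless per record: the artifact reference is synthesized from the
    record being transformed, so ``fit`` only validates parameters.
    """

    def __init__(self, fs: float = 200.0, lowpass_pass_hz: float = 4.0,
                 lowpass_stop_hz: float = 8.0, lowpass_min_atten_db: float = 20.0,
                 dc_pole: float = 0.992,
                 pulsatile_hz: tuple[float, float] = (0.5, 4.0),
                 respiratory_hz: tuple[float, float] = (0.2, 0.35),
                 lms_order: int = 16, lms_mu: float = 0.001,
                 lms_normalize_mu: bool = True, lms_passes: int = 3):
        self.fs = fs
        self.lowpass_pass_hz = lowpass_pass_hz
        self.lowpass_stop_hz = lowpass_stop_hz
        self.lowpass_min_atten_db = lowpass_min_atten_db
        self.dc_pole = dc_pole
        self.pulsatile_hz = pulsatile_hz
        self.respiratory_hz = respiratory_hz
        self.lms_order = lms_order
        self.lms_mu = lms_mu
        self.lms_normalize_mu = lms_normalize_mu
        self.lms_passes = lms_passes

    def fit(self, X, y=None):
        _as_ppg(X, self.fs)
        baselines.FftLmsBands(tuple(self.pulsatile_hz),
                              tuple(self.respiratory_hz)).validate(self.fs)
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        pre = self._preprocess(_as_ppg(X, self.fs))
        bands = baselines.FftLmsBands(tuple(self.pulsatile_hz),
                                      tuple(self.respiratory_hz))
        lp = LmsParams(order=self.lms_order, mu=self.lms_mu,
                       normalize_mu=self.lms_normalize_mu)
        return np.column_stack([
            baselines.fft_lms(pre.red, bands, lp, self.lms_passes).samples,
            baselines.fft_lms(pre.ir, bands, lp, self.lms_passes).samples,
        ])


class MovingAverageDenoiser(TransformerMixin, BaseEstimator, _PreprocMixin):
    """Per-channel centered moving-average baseline as a transformer."""

    def __init__(self, fs: float = 200.0, window_s: float = 0.1,
                 lowpass_pass_hz: float = 4.0, lowpass_stop_hz: float = 8.0,
                 lowpass_min_atten_db: float = 20.0, dc_pole: float = 0.992):
        self.fs = fs
        self.window_s = window_s
        self.lowpass_pass_hz = lowpass_pass_hz
        self.lowpass_stop_hz = lowpass_stop_hz
        self.lowpass_min_atten_db = lowpass_min_atten_db
        self.dc_pole = dc_pole

    def fit(self, X, y=None):
        _as_ppg(X, self.fs)
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        pre = self._preprocess(_as_ppg(X, self.fs))
        return np.column_stack([
            baselines.maf(pre.red, self.window_s).samples,
            baselines.maf(pre.ir, self.window_s).samples,
        ])
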