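"""Least-mean-squares adaptive filtering.

The three-line stochastic-gradient recursion

.. math:: y(n) = w(n)^T u(n), \\quad e(n) = d(n) - y(n), \\quad
          w(n+1) = w(n) + \\mu\\, e(n)\\, u(n)

with a tapped-delay-line input vector
``u(n) = [u(n), u(n-1), ..., u(n-L+1)]`` (zero pre-history). Two roles in
this package: generic noise cancellation, and restoring channel-specific
amplitude to the unit-variance component the constrained-ICA step returns —
with a signal-correlated reference the filter *output* is the recovered
signal and the *error* is the artifact estimate.

With ``normalize_mu`` the effective step is ``mu / (L * P_u + delta)``
where ``P_u`` is the instantaneous input power ``||u(n)||^2 / L`` (NLMS),
making ``mu`` unit-free; plain LMS remains available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .timeseries import TimeSeries

__all__ = ["LmsParams", "LmsResult", "lms", "lms_multipass", "recover_amplitude"]

_DIVERGENCE_FACTOR = 1e6
_NLMS_DELTA = 1e-8


@dataclass(frozen=True)
class LmsParams:
    """Adaptive-filter parameters: tap count L, step size mu, NLMS switch."""

    order: int = 16
    mu: float = 0.05
    normalize_mu: bool = True
    w_init: np.ndarray | None = None
    track_weights: bool = False

    def validate(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be non-negative (0 freezes the taps)")
        if self.w_init is not None and np.asarray(self.w_init).shape != (self.order,):
            raise ValueError("w_init must have shape (order,)")


@dataclass(frozen=True)
class LmsResult:
    """Filter output y, error e = d - y (exact), and tap diagnostics."""

    y: TimeSeries
    e: TimeSeries
    w_final: np.ndarray
    w_trace: np.ndarray | None
    diverged: bool


def lms(u: TimeSeries, d: TimeSeries, params: LmsParams | None = None) -> LmsResult:
    """Run the LMS recursion of the reference input ``u`` against ``d``."""
    params = params or LmsParams()
    params.validate()
    if len(u) != len(d) or u.fs != d.fs:
        raise ValueError("u and d must share length and sampling rate")
    L = params.order
    n = len(u)
    if L >= n:
        raise ValueError(f"order ({L}) must be smaller than the record ({n})")

    upad = np.concatenate([np.zeros(L - 1), u.samples])
    # row k = [u(k), u(k-1), ..., u(k-L+1)]
    U = sliding_window_view(upad, L)[:, ::-1]
    darr = d.samples
    w = (np.zeros(L) if params.w_init is None
         else np.asarray(params.w_init, float).copy())
    scale0 = max(1.0, float(np.linalg.norm(w)))
    y = np.empty(n)
    e = np.empty(n)
    trace = np.empty((n, L)) if params.track_weights else None
    mu = params.mu
    diverged = False
    for k in range(n):
        uk = U[k]
        yk = float(w @ uk)
        ek = darr[k] - yk
        y[k] = yk
        e[k] = ek
        if trace is not None:
            trace[k] = w
        step = mu / (uk @ uk + _NLMS_DELTA) if params.normalize_mu else mu
        w = w + step * ek * uk
        if not diverged and np.linalg.norm(w) > _DIVERGENCE_FACTOR * scale0:
            diverged = True
    return LmsResult(
        y=TimeSeries(y, u.fs) if np.all(np.isfinite(y)) else _nonfinite_ts(y, u.fs),
        e=TimeSeries(e, u.fs) if np.all(np.isfinite(e)) else _nonfinite_ts(e, u.fs),
        w_final=w,
        w_trace=trace,
        diverged=diverged,
    )


def _nonfinite_ts(arr: np.ndarray, fs: float) -> TimeSeries:
    # a diverged run may produce inf/nan; clip so the container stays valid
    return TimeSeries(np.nan_to_num(arr, nan=0.0, posinf=1e30, neginf=-1e30), fs)


def lms_multipass(u: TimeSeries, d: TimeSeries,
                  params: LmsParams | None = None,
                  n_passes: int = 1) -> LmsResult:
    """Repeated LMS sweeps over a fixed record, warm-starting the taps.

    Record-based (offline) denoising permits re-running the recursion with
    the previous pass's final taps as the next initial taps: the first
    sweeps absorb the convergence transient and later sweeps run near the
    steady state, so a small step size — needed to keep in-band artifact
    out of the tap adaptation — still reaches its operating point within
    one record. The returned outputs are from the final pass, so
    ``e = d - y`` holds exactly.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    params = params or LmsParams()
    res = lms(u, d, params)
    for _ in range(n_passes - 1):
        params = LmsParams(order=params.order, mu=params.mu,
                           normalize_mu=params.normalize_mu,
                           w_init=res.w_final,
                           track_weights=params.track_weights)
        res = lms(u, d, params)
    return res


def recover_amplitude(
    corrupted: TimeSeries,
    ppg_component: TimeSeries,
    params: LmsParams | None = None,
    n_passes: int = 1,
) -> tuple[TimeSeries, TimeSeries]:
    """Restore channel amplitude to a unit-variance PPG component.

    Runs LMS with the component as reference ``u`` and the corrupted
    channel as desired ``d``. The filter output tracks the part of ``d``
    correlated with the component — the PPG at the channel's own scale —
    and the error is the artifact estimate. The two outputs sum to the
    input exactly.
    """
    res = lms_multipass(ppg_component, corrupted, params, n_passes)
    return res.y, res.e
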