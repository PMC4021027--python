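# Methods

`ppgclean` removes motion artifacts (MA) from two-channel (red / infrared)
photoplethysmographic (PPG) recordings while preserving each channel's
amplitude scale. Amplitude matters because pulse oximetry computes SpO2
from the relative AC amplitudes of the two channels; a denoiser that
returns a unit-variance waveform is useless for that purpose. The package
combines two classical tools so that each fixes the other's weakness:
one-unit ICA with a temporal reference (constrained ICA, "cICA") extracts
an artifact-free pulse component but loses scale; an LMS adaptive filter
restores each channel's scale but needs a clean reference — which the cICA
output provides.

## Signal model and assumptions

The observation is modelled as a linear, instantaneous mixture
`X = A·S` with `S = [s; MA]`: one pulse waveform `s(t)` entering the red
and IR channels with channel-specific gains, and one artifact waveform
entering both channels through a shared coupling. The working assumptions
are:

* the pulse is quasi-periodic with fundamental in the physiological band
  0.5–4 Hz, while the artifact is aperiodic;
* pulse and artifact are statistically independent, and the artifact is
  closer to Gaussian than the spiky pulse waveform;
* the mixture is effectively instantaneous over the record (no convolutive
  mixing).

When the artifact shares the pulse's period, or is strongly dependent on
it, the constrained extraction can lock onto the wrong component — this is
intrinsic to the method, not an implementation limit.

## Pipeline

For a record `(red, ir)` at sampling rate `fs` (default 200 Hz):

1. **Low-pass filtering.** A linear-phase Hamming-window FIR low-pass
   (passband edge 4 Hz, stopband edge 8 Hz, ≥ 20 dB at the stopband edge;
   tap count from the window-method estimate, verified and grown if
   needed) removes wideband instrument noise. It is applied
   forward-backward (zero-phase) so waveform timing is untouched.
2. **Baseline (DC) removal.** The first-order IIR
   `H(z) = (1 − z⁻¹)/(1 − 0.992 z⁻¹)` separates the slowly varying
   baseline from the pulsatile part. Its numerator has an exact zero at
   DC; on a one-minute constant record the measured attenuation is
   ≈ 23 dB. The `remove_dc` primitive is the literal causal recursion;
   the pipeline applies the same transfer function forward-backward,
   because the causal filter's phase lead near a 1.25 Hz fundamental
   alone distorts the waveform by ≈ 17 % RMS, defeating amplitude
   preservation. The zero-phase pass uses padding matched to the
   1/(1 − pole) ≈ 125-sample transient.
3. **Period estimation and reference generation.** The pulse period is the
   lag of the biased autocorrelation peak of the preprocessed IR channel,
   searched over lags corresponding to 0.5–4 Hz. Among local maxima within
   10 % of the tallest the *shortest* lag wins: a quasi-periodic signal
   repeats at every multiple of its period, so the 2T, 3T… peaks are
   near-ties that must not capture the estimate. Parabolic interpolation
   refines the winning lag to sub-sample precision. A rectangular pulse
   train with that period (duty 0.2, standardized to zero mean / unit
   variance) is then *phase-aligned* to the IR channel by scanning one
   period of onset offsets for maximal |correlation| — the closeness
   measure below compares at lag zero, so an unaligned train would carry
   no information (a train locked onto the troughs is as good as one on
   the peaks, since the measure folds sign).
4. **Constrained extraction.** See below. Output: one unit-variance
   component `y(t)` close to the reference.
5. **Amplitude recovery.** Per channel, an LMS adaptive filter with the
   component as reference input and the preprocessed corrupted channel as
   desired signal; the filter output is the recovered channel (the part of
   the channel correlated with the pulse component, at the channel's own
   scale) and the error is the artifact estimate. The two outputs sum to
   the preprocessed input exactly, sample by sample.

## Constrained one-unit ICA

After whitening (eigendecomposition of the channel covariance; a
rank-deficient covariance — perfectly correlated channels — is an error),
the solver maximises the negentropy surrogate

    J(y) ≈ ρ · (E[G(wᵀz)] − E[G(v)])²,   y = wᵀz,  ‖w‖ = 1,

with `G(u) = log cosh u` by default (`exp` and `kurtosis` are available),
`v` standard Gaussian (`E[G(v)]` precomputed by quadrature), subject to
the closeness constraint `ε(y, r) − ξ ≤ 0` with

    ε(y, r) = 2 · (1 − |corr(y, r)|),

the mean squared error between standardized signals after sign-alignment.
Unit norm of `w` on whitened data enforces unit variance of `y` exactly.

Numerical scheme:

* **Augmented Lagrangian** with a scalar multiplier and quadratic penalty
  on the (linear-in-`w`) inequality; multiplier updated every iteration.
* **Newton-like step**: the FastICA fixed-point direction
  `β(E[z g(y)] − E[g′(y)] w) + 2λ·sign(wᵀc)·c`, where `c = E[z r̃]` is the
  reference cross-correlation vector (so `corr(y, r) = wᵀc`), renormalized
  each step; `β = 2ρ(E[G(y)] − E[G(v)])` orients the step up the gradient.
* **Damped acceptance**: the raw step is backtracked along the sphere
  until the augmented merit does not decrease — undamped fixed-point steps
  overshoot badly where the negentropy surface is flat.
* **Multi-start**: the constrained problem is multimodal (sampling noise
  alone gives spurious negentropy to noise-dominated directions), so the
  solver runs from the reference direction `c/‖c‖` plus seven directions
  spanning the whitened sphere, and keeps the best *feasible* solution by
  negentropy (falling back to smallest closeness if none is feasible).
  Convergence of a run is declared when the undamped update is already a
  fixed point (`|⟨w₊, w⟩| > 1 − tol`, tol `1e-7`); non-convergence is
  flagged in the result, never raised.
* **Adaptive threshold**: when `ξ` is not given it is set to
  `2(1 − ‖c‖) + 0.1`, clipped to [0.1, 1.9] — a small margin above the
  closeness of the most reference-correlated direction attainable, which
  keeps the constraint active without infeasibility. The feasible-set
  boundary attracts the solution, so a tight margin pins the output to
  the reference-correlated pulse.

The reference resolves ICA's permutation ambiguity (a reference built at
the artifact's period extracts the artifact instead — tested), and the
amplitude-recovery stage resolves the scale ambiguity.

## LMS adaptive filtering

The three-line recursion `y(n) = w(n)ᵀu(n)`, `e(n) = d(n) − y(n)`,
`w(n+1) = w(n) + μ e(n) u(n)` over a tapped delay line of `L` samples,
zero pre-history, with optional normalized stepping
(`μ/(‖u(n)‖² + δ)`, NLMS) making `μ` unit-free. `μ = 0` freezes the taps;
negative `μ` is an error. Divergence (tap norm exceeding 10⁶ × its initial
scale) is flagged, not raised.

Defaults for the *pipeline role*: `L = 16`, NLMS `μ = 0.001`, and three
passes over the record with taps warm-started from the previous pass
(`lms_multipass`). The small step is deliberate: the artifact overlaps the
pulse band, and a fast-adapting filter tracks artifact-harmonic beats into
its output (measured ≈ 90 % RRMSE at 0 dB even with an oracle reference);
a slow filter averages them out but needs longer than one 20 s record to
converge from zero taps — re-sweeping the fixed record supplies that
length. Offline, record-based operation makes this legitimate; the
streaming-style primitive `lms()` keeps a conventional `μ = 0.05`.

In the combined method the reference is *signal*-correlated, so the
recovered channel is the filter **output**. In the spectral-subtraction
baseline below the reference is *noise*-correlated, so the recovered
channel is the **error**.

## Baselines

* **Spectral-subtraction LMS** (`fft_lms`): one full-record DFT of the
  corrupted channel; bins in the pulsatile band (0.5–4 Hz) and the
  respiratory band (0.2–0.35 Hz), edges inclusive, are zeroed (negative
  frequencies mirrored, so the inverse transform is real); the inverse
  transform is the artifact reference fed to LMS. It can only cancel
  artifact energy *outside* the protected bands — its weakness against
  in-band artifacts is the point of the comparison.
* **Moving-average filter** (`maf`): centered box window, length
  `round(window_s · fs)` forced odd (default 0.1 s), edges handled by
  shrinking the window. Preserves constants and respects input bounds.

## Synthetic data

The generator emulates the study conditions of the synthetic benchmark:

* **Clean pulse**: sum of `n_harmonics = 4` sinusoid harmonics with decay
  0.5 per harmonic, plus a delayed (0.35 of a cycle) copy attenuated to
  0.45 as a dicrotic-wave surrogate; cycle-to-cycle period jitter 2 %
  (Gaussian, clipped at ±2.5 σ) through piecewise-linear phase
  accumulation. Both channels carry the *same* waveform; the red channel
  is scaled so RMS(red)/RMS(ir) equals the amplitude ratio (default 0.6)
  exactly. Independent per-channel sensor noise at 1 % RMS keeps
  artifact-free records full-rank for whitening. A deterministic
  morphology difference between channels was rejected: it constitutes an
  ICA-separable source pair of its own, and the extraction then returns
  an elementary waveform instead of the pulse.
* **Artifacts** (all zero-mean, unit RMS, seeded): band-limited Gaussian
  noise via spectral shaping on [0.1, 4] Hz by default — inside the pulse
  band, the regime where fixed filtering fails; a linearly detrended
  random walk; randomly timed smooth bumps (Poisson rate 0.5 Hz, 0.3 s
  width); or an equal-weight composite. These are surrogates chosen to
  span slow drifts and transient excursions; they claim no fidelity to
  any particular recording hardware or motion type.
* **Mixing**: `mix_at_snr` implements `x = s + λ·MA` with
  `λ = RMS(s)/(RMS(MA)·10^(SNR/20))`, exact by construction.
  `mix_two_channel` adds the *same* `λ·MA` to both channels with `λ`
  computed from the IR channel: a single artifact column keeps the
  two-source mixing invertible. Scaling the artifact per channel so both
  meet the same SNR would make the artifact column proportional to the
  pulse column — then no linear unmixing can separate them (the red
  mixture becomes an exact multiple of the IR mixture). The red channel
  therefore sits at `SNR + 20·log10(amplitude ratio)` ≈ 4.4 dB below the
  requested level with the default ratio.
* **Score**: `RRMSE = 100·RMS(s − ŝ)/RMS(s)` in percent; the RMS is
  uncorrected (no detrending), and the score deliberately reports scale
  errors: `rrmse(s, a·s) = 100·|1 − a|`.

What passing tests on this generator do **not** show: robustness to
artifacts dependent on the pulse, to convolutive (multi-path) mixing, to
waveform morphology changes within a record, or to real sensor
nonlinearities. The benchmark isolates the linear-mixture mechanism the
method targets.

## Monte-Carlo benchmark

Per (SNR, replicate): a fresh pulse record (heart rate uniform on
0.9–1.6 Hz, 20 s at 200 Hz) and artifact realisation, both channels mixed
as above, each method run on the same preprocessed record, RRMSE per
channel against the clean source with the first 2 s (filter transient)
excluded. The package default grid is −10 … +10 dB in 1 dB steps with 30
replicates per level — the benchmark size shipped with the test suite;
the command-line `evaluate` defaults to 100 replicates. All seeds derive
from a single master seed (`numpy.random.SeedSequence`), making tables
bit-reproducible. Method failures are recorded as missing cells, not
crashes.

Typical behaviour (master seed 7): the combined method's mean RRMSE is
below both baselines at every grid point on both channels, e.g. at 0 dB
(IR) roughly 30 % against ≈ 100 % for the baselines, which barely improve
on the raw mixture because the default artifact lies almost entirely
inside the protected pulse band.

## Amplitude metric

`peak_to_peak_stats` cuts a record into consecutive windows of one
estimated period and reports mean ± SD of per-window max − min — the
quantity SpO2 estimation consumes. On synthetic mixtures at 0 dB the
recovered records' peak-to-peak means track the clean records' within
25 % and are closer to them than the corrupted mixtures' (tested).

## Numerical choices and degenerate inputs

* Whitening rejects covariance eigenvalue ratios below 1e−10.
* `estimate_period` requires ≥ 3 cycles at the slowest admissible rate and
  rejects all-zero records; `make_reference` requires 1 < period < n and
  duty in (0, 1).
* Records shorter than 10 s are rejected by the pipeline.
* The scoring window skip (2 s) and every band edge, pole, duty, and LMS
  parameter are config keys (`PipelineConfig` / YAML) with the defaults
  above.

## Known limitations

* On artifact-free records the extraction has no artifact to null; the
  component is then whichever direction maximises the constrained
  criterion, and end-to-end transparency is ≈ 14–21 % RRMSE rather than
  the preprocessing floor (≈ 7 %). The method presumes corrupted input.
* Below ≈ −7 dB the period estimate occasionally locks onto an artifact
  autocorrelation lag; the reference then carries no pulse information
  and the record passes through essentially unchanged (the failure is
  benign — output ≈ input — but not an improvement).
* One component is extracted; artifact energy spanning more than one
  independent source beyond the pulse stays in the residual, which is the
  desired behaviour for cleaning but means the artifact *estimate* is not
  itself a single physical source.
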