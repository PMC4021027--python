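# ppgclean

Motion-artifact removal for two-channel (red / infrared)
photoplethysmographic (PPG) recordings, with the amplitude information
preserved.

Pulse oximeters estimate arterial oxygen saturation (SpO2) from the
relative AC amplitudes of the red and IR PPG channels, so a denoiser must
return each channel at its own scale — and motion artifacts (MA) overlap
the pulse band (0.5–4 Hz), so fixed-cutoff filtering cannot remove them.
`ppgclean` implements a combined method for this problem, for researchers
and engineers working on pulse-oximetry signal quality:

1. **Constrained ICA (cICA / ICA-with-reference).** Model the two channels
   as a linear mixture `X = A·S` of a pulse source and an artifact source.
   A one-unit ICA maximises the negentropy surrogate
   `J(y) ≈ ρ·(E[G(wᵀx)] − E[G(v)])²` subject to
   `g(w) = ε(y, r) − ξ ≤ 0` and `h(w) = E[y²] − 1 = 0`, where `r` is a
   rectangular pulse train at the pulse period estimated by
   autocorrelation. The reference pins down *which* component comes out
   (no permutation ambiguity), and the unit-variance constraint bounds the
   contrast — but the component carries no amplitude.
2. **LMS amplitude recovery.** The recursion `y(n) = w(n)ᵀu(n)`,
   `e(n) = d(n) − y(n)`, `w(n+1) = w(n) + μ e(n) u(n)` with the extracted
   component as reference `u` and each corrupted channel as desired signal
   `d`: the filter output is the artifact-free channel at its own scale,
   the error is the artifact estimate, and the two sum to the input
   exactly.

Two comparison methods are included: spectral-subtraction LMS (zero the
pulsatile 0.5–4 Hz and respiratory 0.2–0.35 Hz bands of the record's
spectrum, inverse-transform, use the remainder as a noise reference for
LMS) and a centered moving-average filter. A seeded synthetic-data module
generates quasi-periodic pulse records and artifact surrogates, mixes them
at exact SNRs (`x = s + λ·MA`, `SNR = 20·log10(RMS(s)/RMS(λ·MA))` dB),
and scores reconstructions by `RRMSE = 100·RMS(s − ŝ)/RMS(s)` (percent).

## Worked example

```python
import numpy as np
from ppgclean import (ArtifactModelParams, PpgModelParams, TimeSeries,
                      denoise_cica_lms, generate_artifact, generate_clean_ppg,
                      mix_two_channel, peak_to_peak_stats, rrmse)

clean = generate_clean_ppg(PpgModelParams(heart_rate_hz=1.25, seed=0))
artifact = generate_artifact(ArtifactModelParams(seed=100))
mixed, lam, snrs = mix_two_channel(clean, artifact, snr_db=0.0)
out = denoise_cica_lms(mixed)

def score(c, r, skip=400):   # skip the 2 s adaptive-filter transient
    return rrmse(TimeSeries(c.samples[skip:], c.fs),
                 TimeSeries(r.samples[skip:], r.fs))

print(f"estimated pulse period     : {out.period.period_samples:.1f} samples")
print(f"component variance         : {np.var(out.cica.y.samples):.6f}")
print(f"RRMSE corrupted  (red, ir) : {score(clean.red, mixed.red):.1f} %, "
      f"{score(clean.ir, mixed.ir):.1f} %")
print(f"RRMSE recovered  (red, ir) : {score(clean.red, out.recovered_red):.1f} %, "
      f"{score(clean.ir, out.recovered_ir):.1f} %")
p = peak_to_peak_stats(out.recovered_ir, out.period)
print(f"IR peak-to-peak recovered  : {p.mean:.2f} +/- {p.sd:.2f}")
```

prints

```
estimated pulse period     : 159.5 samples
component variance         : 1.000000
RRMSE corrupted  (red, ir) : 167.0 %, 100.2 %
RRMSE recovered  (red, ir) : 18.8 %, 14.7 %
IR peak-to-peak recovered  : 2.38 +/- 0.16
```

The period estimate matches the generated 1.25 Hz pulse (160 samples at
200 Hz); the extracted component has unit variance by construction; the
relative error of both channels drops from 167 % / 100 % to 19 % / 15 %;
and the recovered per-cycle peak-to-peak amplitude (2.38) sits close to
the clean record's (2.48 ± 0.01) — the quantity SpO2 estimation needs.
(The red channel starts worse than IR because the single artifact
waveform is scaled to put the *IR* channel at the requested 0 dB, and the
red channel has the smaller pulse amplitude.)

## scikit-learn-style interface

Records are `(n_samples, 2)` arrays with columns (red, ir):

```python
from ppgclean import CicaLmsDenoiser
X = np.column_stack([mixed.red.samples, mixed.ir.samples])
den = CicaLmsDenoiser(fs=200.0)
X_clean = den.fit_transform(X)        # (n, 2), denoised
den.period_, den.cica_result_.closeness
```

`FftLmsDenoiser` and `MovingAverageDenoiser` expose the baselines with the
same contract; all three support `get_params` / `set_params` / `clone` and
compose in sklearn pipelines.

## Command line

```bash
ppgclean simulate --out sim/ --snr-db 0 --seed 5          # fixture CSVs + JSON sidecar
ppgclean denoise --in sim/mixture.csv --method cica-lms --out recovered.csv
ppgclean evaluate --snr-min -10 --snr-max 10 --snr-step 1 \
                  --reps 100 --methods all --seed 7 --out table.csv
```

CSV dialects: `t,red,ir` (two-channel) or `t,signal` (single-channel),
header required; the sampling rate is inferred from `t` or given with
`--fs`. Pipeline parameters can be overridden with a YAML file
(`--config`); see `ppgclean.config.PipelineConfig` for the keys.

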