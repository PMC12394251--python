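# Methods

This note documents the models, numerical choices and validation logic of
the `fpvs` package: what each stage computes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Signal model

A frequency-tagging trial is modelled as a sum of stimulus-locked
sinusoids on the 64 scalp channels:

```
x_ch(t) = Σ_k a_k w_base[ch] sin(2π k f_b t + φ_k)
        + Σ_m b_m w_odd[ch] sin(2π m f_o t + ψ_m)        (harmonics ≤ 48 Hz)
```

multiplied by the linear contrast-ramp envelope of the stimulation
sequence, plus additive 1/f^α background noise, white noise, 50 Hz line
noise, and stereotyped blink transients.  `f_b` is the image-presentation
("base") rate, `f_o = 1 Hz` the oddball rate; oddball harmonics that
coincide with base harmonics carry no separate amplitude.  Topographies
`w` are per-channel weights in [0, 1] — deliberately *not* dipole
projections; there is no head model.  Phases are drawn once per trial per
harmonic and shared across channels (a coherent field).  Per-channel
amplitude analyses are insensitive to this choice; it only fixes the
cross-channel phase structure, and a coherent field is the physically
conservative option.

The 48 Hz cap is inclusive (a harmonic at exactly 48 Hz counts).

## Preprocessing chain and numerical choices

Order: interpolate listed noisy channels → downsample → notch → band-pass
→ ocular regression → common average reference → steady-state trim.

* **Filters are zero-phase** (forward–backward `sosfiltfilt`), so the
  effective magnitude response is the square of one pass.  Group delay
  would smear trial boundaries; amplitude analysis must not pay that
  cost.  Tests check the squared analytic responses.
* **Downsampling** (factor 4, 1024 → 256 Hz) applies an 8th-order
  Butterworth guard filter at 0.8× the new Nyquist (102.4 Hz) before
  decimation: the 0.05–100 Hz analysis band passes essentially untouched
  while everything that could alias is suppressed.  Event indices divide
  by the factor (floor).
* **Notch**: 2 Hz-wide zero-phase band-stops.  At 256 Hz only 50 and
  100 Hz exist; a 150 Hz line harmonic is above Nyquist and cannot alias
  in past the guard filter, so the default chain notches only
  representable centers.  `notch()` itself rejects centers ≥ Nyquist.
* **Ocular regression** uses bipolar regressors HEOG = HEOG_L − HEOG_R
  and VEOG = VEOG_U − VEOG_L, demeaned, with per-channel least-squares
  propagation coefficients estimated over the whole continuous recording.
  Classical implementations estimate coefficients on blink-locked
  averages; the whole-recording fit is simpler and satisfies the same
  testable contract (residual covariance with the regressors ≈ 0).  The
  mean-centered regression leaves a DC offset per channel; DC is
  irrelevant to every downstream quantity.  A zero-variance regressor is
  skipped with a warning.
* **Average reference** zeroes the mean over the 64 scalp channels at
  every sample; ocular channels are excluded and left unreferenced.
  Note the consequence for simulations: a coherent source with
  topography `w` appears after referencing with effective topography
  `w − mean(w)`.  All recovery comparisons use this projected value.
* **Trimming** retains exactly `steady_samples` (14 337 for the 60 s
  designs, 23 041 for the 90 s design — the printed counts, which are one
  sample longer than an integer number of seconds).  The window anchors
  at onset + ramp for the 2 s-ramp design and at onset for the others, a
  config-driven choice: the 5 s-ramp design's printed count does not fit
  after its ramp, so its window necessarily includes the ramp.  The ramp
  multiplies signal only, never noise.

## Spectral quantification

Amplitude normalisation is 2|X_k|/N (|X_k|/N at DC and Nyquist), so
amplitudes read in µV of the underlying sinusoid.  Trial spectra are
averaged *before* baseline correction (enforced by a flag; correcting
first is a different computation on noisy data).  The baseline window
spans bin offsets ±2..±11 and truncates (never wraps) at spectrum edges,
preserving the ±1 exclusion zone.  Harmonic windows are the nearest bin
±1 adjacent bin — the stimulation frequency can drift by about one bin
width between recording sessions — and base bins take precedence when
windows collide (oddball bins inside a base window are dropped).

### Known bias of the summed-magnitude estimator

The baseline subtracts the local mean *magnitude* of noise bins.  At a
bin carrying true amplitude `a` in complex noise with per-quadrature
scale σ, the corrected value estimates approximately
`sqrt(a² + 2σ²) − σ√(π/2)`: biased low by ≈ 1.25 σ even at high SNR, and
collapsing toward 0 when `a ≲ σ`.  Consequences:

* noiseless recovery is exact (σ = 0) — the end-to-end tests show the
  filter chain transparent to < 1%;
* in noise, harmonics below the per-bin noise floor contribute nothing
  to the recovered sum, so a decaying harmonic series is *structurally*
  under-recovered at low SNR.

The stochastic recovery validation therefore injects a uniform 1 µV
oddball comb with a focal ROI topography: every summed bin then clears
the noise floor and the predicted bias (≈ −12% at 10 µV pink noise,
4 averaged trials) stays inside the 15% validation band — measured
median recovery ≈ 0.91.  This is a property of the estimator itself, not
of the simulation.

## Synthetic-data generator

Defaults represent one plausible recording condition, chosen once:
fundamental base amplitude 1 µV and oddball 0.5 µV with geometric decay
0.7 per harmonic (the decaying series typical of steady-state responses);
pink noise α = 1 at 10 µV; white noise 1 µV; 50 Hz line at 2 µV; blinks
at 6/min, 100 µV, biphasic ~300 ms kernel, propagating to scalp channels
with a frontally weighted gradient (≤ 0.4).  Base topography is
medial-occipital (Gaussian around Oz/POz), oddball topography bilateral
occipito-temporal (around PO7/PO8).  Duty-cycle effects are emulated by
amplitude attenuation factors (halved duty: base ×0.65; doubled rate:
base ×0.45, oddball ×0.6) rather than by rendering stimuli — the
phenomenon of interest in that design *is* an amplitude change.

What the generator does **not** emulate: real image-evoked transients and
their non-sinusoidal waveshape, inter-channel noise correlations and
volume conduction, alpha rhythms and other narrowband oscillators,
electrode drift, muscle artifacts, and any dependence of topography on
frequency.  Passing parameter-recovery tests therefore demonstrates that
the *pipeline* is correct and calibrated, not that it would behave
identically on any particular real recording.

## Decoding

Features are the 64 baseline-corrected scalp amplitudes of each 1 s epoch
at one integer frequency (1–47 Hz).  Each repetition draws a stratified
60/40 split; scaler and PCA (20 components, full SVD for determinism) are
fitted on training rows only; the ridge penalty is selected by 3-fold CV
inside the training set over 10 log-spaced values in [1e−3, 1e3]
(transformers refitted per fold — no validation leakage); one logistic
model per class pair votes on the held-out 40%, ties broken toward the
lowest class index (a deterministic rule; sklearn's own one-vs-one breaks
ties by confidence).  The summary is the median accuracy over
repetitions; chance is 1/n_conditions.  The repeated-holdout reading (CV
used only for penalty selection, accuracy from the 40% holdout) is one of
two defensible interpretations of the procedure; it is the one that makes
"tested on the remaining 40%" literal.

## Group statistics

Five candidate models of the ROI response (null, +group, +condition,
both, interaction), each a linear mixed model with a subject random
intercept fitted by ML.  Random slopes are intentionally omitted: with
~15 subjects and 2–4 conditions they are unidentifiable.  Evidence is the
BIC approximation log BF₁₀ = (BIC₀ − BIC₁)/2 with k = fixed effects +
random-intercept variance + residual variance; posterior model
probabilities assume a uniform prior.  This is a large-sample surrogate
for a fully Bayesian ANOVA, so its behaviour is established empirically
rather than assumed: at n = 7 + 8 with 4 conditions, 100 null simulations
prefer the null in > 70 cases, a 2-residual-SD condition effect is
detected (log BF₁₀ > log 10) in > 90, and spurious strong group evidence
stays ≤ 15%.  All BFs are scale-invariant (location-scale family; checked
numerically to 1e−6).  Non-converged or singular fits are flagged and
excluded from the posterior normalisation.

Post-hoc paired comparisons and the per-frequency accuracy comparisons
(group vs group, grand average vs chance) use the same BIC approximation
on one- and two-sample Gaussian models.

## Problem sizes

The test suite and the acceptance script use: 20 seeds × 4 trials for
stochastic recovery; 100 repetitions for decoding calibration and
separability; 100 simulations for Bayes-factor calibration and power at
n = 7 + 8.  The demonstration cohort under `analysis/` uses 3 + 3
subjects and 2 trials per condition — deliberately small, sized so the
full five-script pipeline (including writing and re-reading 48 BDF files)
completes in a few minutes.

## Limitations

* BDF writing clips amplitudes outside ±3276.8 µV and requires
  integer-second recordings (one-second data records).
* The 1 Hz-bin epoch spectra give the decoder only 47 usable frequencies;
  epoch-level baseline correction at edge bins uses truncated windows,
  the same convention as whole-trial spectra.
* The BIC Bayes factors are asymptotic; at these sample sizes they are
  conservative relative to full Bayesian ANOVA and should be read through
  the calibration figures above.
* No automated artifact rejection (ICA, bad-trial exclusion) — out of
  scope by design; noisy channels are interpolated from a manual list.
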