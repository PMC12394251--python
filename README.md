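# fpvs — frequency-tagged EEG oddball analysis

`fpvs` implements the analysis pipeline for fast periodic visual
stimulation (FPVS) EEG experiments: stimuli stream at a *base* rate
(e.g. 6 images/s) with a deviant *oddball* embedded periodically (here
1 Hz).  Stimulus-locked cortical responses concentrate at the stimulation
frequencies and their harmonics, so discrimination of the deviant property
is read directly out of the EEG amplitude spectrum — no behavioural
response needed.  The package is aimed at researchers who want a tested,
fully scriptable version of this workflow, plus a synthetic-EEG generator
that makes every stage verifiable by parameter recovery when no recordings
are available.

## What it computes

For a steady-state trial of $N$ samples at $f_s = 256$ Hz, the one-sided
amplitude spectrum $A(f_k)$ ($f_k = k f_s / N$, unit sinusoid → 1 µV) is
averaged across trials per condition, then baseline-corrected per bin:

$$A_c(f_k) = A(f_k) - \mathrm{mean}\{A(f_{k+j}) : 2 \le |j| \le 11\}$$

(the two adjacent bins are excluded because signal leaks into them).  The
responses are harmonic sums up to 48 Hz, each harmonic taken with its two
adjacent bins:

* **base response** = $\sum A_c$ over bins at $k\,f_{base}$,
* **oddball response** = $\sum A_c$ over bins at $m\,f_{odd}$, excluding
  every bin already claimed by the base response,

summarised per channel and averaged over a bilateral parieto-occipital ROI
(PO7, PO8, P7, P8, P9, P10).  One-second epochs give 1 Hz-resolution
spectra for per-frequency multivariate decoding (scaling → 20-component
PCA → ridge-penalised logistic regression, penalty chosen by inner 3-fold
CV over 10 values in $[10^{-3}, 10^3]$, one-vs-one majority voting,
median test accuracy over repeated stratified 60/40 splits).  Group-level
evidence uses linear mixed models (subject random intercept, ML) compared
through the BIC approximation $\log \mathrm{BF}_{10} =
(\mathrm{BIC}_0 - \mathrm{BIC}_1)/2$.

Preprocessing follows the standard chain: noisy-channel interpolation
(3 nearest neighbours), 1024 → 256 Hz downsampling, 50/100 Hz notch,
0.05–100 Hz fourth-order Butterworth band-pass (all zero-phase),
regression-based ocular correction from 4 EOG electrodes, common average
reference, steady-state trimming.

## Worked example

The numbered scripts under `analysis/` run a reduced demonstration cohort
(3 controls + 3 super-recognizers, identity-discrimination design with
base rates 3/6/9/12 Hz, 2 trials per condition) end to end:

```bash
python analysis/01_simulate.py      # synthetic recordings -> BDF (scratch/)
python analysis/02_preprocess.py    # full chain -> steady-state segments
python analysis/03_spectra.py       # harmonic sums -> results/harmonic_summaries.tsv
python analysis/04_decode.py        # per-frequency decoding -> results/
python analysis/05_group_stats.py   # mixed-model Bayes factors -> results/
```

Output from a run of steps 03 and 05:

```
mean ROI base response by presentation rate:
     3 Hz:  0.375 uV
     6 Hz:  0.161 uV
     9 Hz:  0.119 uV
    12 Hz:  0.158 uV
base response: best model = condition (log BF10 vs null: {'group': -1.37, 'condition': 4.07})
oddball response: best model = null (log BF10 vs null: {'group': -1.04, 'condition': -2.8})
```

The cohort injects a base response that falls with presentation rate and
an oddball response identical across conditions and groups — and that is
what the pipeline reads back out: the condition-only model wins decisively
for the base response (log BF₁₀ = 4.07 vs the null), while the oddball
response is best explained by the null model.  Single-epoch decoding at
this noise level (10 µV 1/f background vs ≤ 1.4 µV signals) stays barely
above the 0.25 chance level, reflecting the low per-epoch SNR.

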