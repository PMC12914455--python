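# dyadpredict

Measurement and inference pipeline for studies of **caregiver sensory
predictability and infant neurophysiology**: how unpredictable patterns of
caregiver auditory, visual and tactile signals during a dyadic play
interaction relate to an infant's autonomic function (heart-rate
variability), heart-rate-defined sustained attention, and frontal theta EEG
power. It is written for developmental-psychophysiology researchers who
micro-code caregiver behavior (BORIS-style event logs), record infant ECG
and EEG, and fit small-sample regressions under missing data.

## What it computes

**Caregiver entropy rate.** Coded modality on/off events induce a sequence
of composite sensory states (subsets of {auditory, visual, tactile},
including "no signal"). Predictability is the Shannon entropy rate of the
first-order transition sequence,

    H = − Σᵢ πᵢ Σⱼ P(j|i) log₂ P(j|i)   [bits/transition],

with row-normalized empirical transition probabilities `P(j|i)` and
empirical source-state frequencies `π`. Interrater agreement (raw % and
Cohen's κ over time-binned modality presence) validates the coding.

**Baseline HRV.** RMSSD of beat-domain inter-beat intervals (ms), mean heart
rate as its standard covariate, cohort-level 5th/95th-percentile
winsorization, and a 100 Hz interpolated tachogram for spectral extensions.

**Heart-rate-defined sustained attention.** A phase opens when the infant
looks at the stimulus *and* five consecutive IBIs each exceed the median of
the five preceding baseline IBIs; it closes on five consecutive IBIs below
the median of the preceding five; baselines re-seed after each phase.
Indices: total SA duration (s) and mean heart-rate deceleration
(ΔIBI vs the 5-s pre-stimulus baseline, positive = slower heart).

**Frontal theta.** 1-s EEG segments, Hanning-windowed FFT power at 1 Hz
resolution; relative theta = (4–6 Hz power)/(1–50 Hz power) over frontal
channels, per segment, averaged per condition; the attention − inattention
change score is the neural attention index. Segments with frontal peak
amplitude > 3 SD from the median are rejected; < 20 usable segments ⇒
missing value.

**Inference.** Full-information maximum-likelihood (FIML) regression:
EM over missingness patterns for the multivariate-normal observed-data
likelihood, standardized coefficients from model-implied moments, expected
(Fisher) information SEs with a small-sample t calibration. Robustness
checks: sandwich SEs, chained-equation multiple imputation (normal-linear,
Rubin-pooled), listwise OLS. Plus covariate screening at p < .10, Little's
MCAR test, quadratic and sex-moderation checks, and a design-sensitivity
(minimal detectable effect) analysis by noncentral-F inversion.

A synthetic-dyad generator (Markov caregiver sequences with tunable entropy
rate, AR(1)+respiratory IBI series with calibrated RMSSD and planted
decelerations, 1/f EEG with condition-gated theta gain, structural cohort
model with planted standardized effects and MCAR missingness) makes the
whole chain testable end-to-end without any participant data.

## Worked example

A full synthetic study at the published design scale (104 dyads, ~11–23 %
missingness per variable, planted standardized effects):

```python
from dyadpredict.pipeline import RunConfig, run_pipeline

cfg = RunConfig(n_dyads=104, seed=7, stages=("entropy", "hrv", "fit"))
res = run_pipeline(cfg)
print(res.descriptives.to_string(index=False))
print(res.results[res.results.term == "entropy_bits"].to_string(index=False))
```

prints

```
    variable  n       mean        sd        min        max     skew  kurtosis
entropy_bits 97   0.663072  0.270908   0.124072   1.356080 0.120702 -0.332901
    rmssd_ms 90  10.427841  4.773649   0.889685  19.629267 0.000418 -0.395909
 mean_hr_bpm 87 151.348734 12.429964 121.283670 185.352572 0.168928  0.160205

       model  outcome         term      beta       se        p estimator   n
entropy->hrv rmssd_ms entropy_bits -0.151772 0.099812 0.131585      fiml 104
```

Each dyad's caregiver event log and IBI series were simulated, re-measured
through the entropy and HRV stages, assembled with MCAR masks, and fit by
FIML with mean heart rate, age, sex and gestational age as covariates. The
planted entropy→HRV effect is −0.25; one n=104 sample recovers a noisy,
measurement-attenuated estimate (here −0.15, n.s.) — exactly why the
design-sensitivity analysis below matters. Averaged over many seeds the
estimator is unbiased (see `tests/test_acceptance.py`), and at n=500 the
effect is detected in essentially every run.

The same stages are scriptable from the shell:

```bash
dyadpredict run --outdir out --seed 7 --n-dyads 104
dyadpredict entropy --events out/raw/d0000_events.csv --duration 300 --out ent.csv
dyadpredict hrv --ibi out/raw/d0000_baseline_ibi.csv --out hrv.csv
```

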