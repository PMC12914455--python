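# Methods

This note documents the models, estimators, generator assumptions, numerical
choices and known limitations of `dyadpredict`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Caregiver sensory entropy

Coded events are (modality, onset, offset) intervals over
{auditory, visual, tactile}. At any instant the caregiver occupies the
composite state = set of active modalities (8 possible states including the
empty "no signal" state, which we treat as a real state: transitions into
and out of silence are informative). Intervals are half-open; simultaneous
offsets/onsets are applied jointly so contiguous same-modality coding does
not flicker. Consecutive duplicate states are collapsed, making
self-transitions structurally impossible. Two boundary conventions are
config-isolated:

* `include_leading_empty` (default on): the session starts in the empty
  state at t = 0, so the first signal onset counts as a transition.
* Change points at the session end are truncation artifacts, not
  transitions, and are dropped.

The entropy rate is the plug-in estimator
H = −Σᵢ πᵢ Σⱼ P(j|i) log₂ P(j|i) with π the empirical *source-state*
frequency (not the chain's stationary distribution — sessions are 5-min
finite samples), 0·log 0 = 0, no smoothing or pseudocounts, and rows with no
outgoing transitions contributing zero. Units are bits (log base 2), giving
the 0–3 bit working range natural for ≤ 8 states. The plug-in estimator is
biased downward at short sequence length (≈150 transitions per 5-min
session over up to 56 transition cells); this attenuates, but does not
distort the sign of, cohort-level associations — visible in the end-to-end
recovery tests.

Interrater reliability discretizes the session into 1-s bins (configurable)
and compares binary modality presence: raw agreement = % matching bins,
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from marginal rates, both
averaged over the three modalities. When p_e = 1 (both coders constant) κ is
defined as 1 if the constants agree, else 0.

## Cardiac metrics

RMSSD is computed on the **beat-domain** IBI sequence,
√mean((IBIₖ₊₁ − IBIₖ)²). Interpolating to a uniform grid before a
successive-difference statistic would distort it; the 100 Hz linearly
interpolated tachogram (knots at each interval's closing beat, endpoints
held) is produced and retained for optional spectral extensions but is not
used for RMSSD. Mean HR = 60000/mean(IBI) and is forced into every model
involving RMSSD by the pipeline's model table, reflecting the mechanical
HR–HRV dependence.

Artifact handling is rule-based only (IBI outside 250–1000 ms or successive
jump > 200 ms → flagged, replaced by linear interpolation over beat index);
manual ECG editing is out of scope. Recordings shorter than 60 s
(configurable) are flagged unusable. Winsorization caps at the 5th/95th
percentiles using the linear-interpolation order-statistic estimator, and is
applied across the cohort's RMSSD values, not within recordings. With this
estimator winsorization is only *approximately* idempotent (a second pass
can move caps within the spacing of adjacent order statistics); it is exact
when caps coincide with data values.

## Sustained attention

IBIs are indexed by their opening beat. Outside a phase, the baseline is the
five most recent IBIs; a phase opens at the first beat of a run of five
consecutive IBIs each **strictly** greater than the baseline median,
provided that first beat lies inside a looking interval. Inside a phase,
five consecutive IBIs each strictly below the median of the five IBIs
immediately preceding the run close it at the run's first beat. Ties never
change state. After closure the baseline re-seeds from the five following
beats. Looking is required only at onset (a within-phase look-away does not
terminate; a flag enables the stricter variant). A phase still open at the
last beat closes at the task-window end. Every emitted phase records its
trigger index and baseline median, so the onset decision is replayable — a
tested invariant. Inattention is all task time not in SA; the two kinds tile
the task window.

Deceleration = mean IBI within SA phases − mean IBI in the 5-s pre-stimulus
window (positive = slower). No SA phases ⇒ missing value, propagated, never
zero.

## EEG spectral analysis

1-s segments (sampling rate × 1 s samples each) are labeled by the phase
containing their midpoint. Per segment and channel: Hanning window, FFT,
one-sided power scaled so the bin sum equals windowed time-domain energy
(Parseval; a Hann-windowed pure tone places 2/3 of its energy in its center
bin and > 99 % in the 3-bin main lobe). Relative theta uses inclusive 1 Hz
bins 4–6 over total band 1–50 (both configurable), power summed over the
frontal channel subset (geodesic electrodes 2, 3, 5, 6, 9–14, 57, 59, 60),
ratio formed **per segment** then averaged per condition — robust to
segment-count imbalance; the log₁₀-of-averaged-band-power alternative is
available behind a flag and log₁₀ band powers are emitted as auxiliary
outputs. Segment rejection: frontal peak |amplitude| beyond 3 SD of the
median ⇒ excluded. Fewer than 20 retained segments ⇒ all spectral outputs
missing. Upstream cleaning (filtering, ICA, bad-channel repair) is assumed
done by standard preprocessing tools and is out of scope.

## FIML regression and companions

The joint vector (predictors, covariates, outcome) is modeled multivariate
normal; EM over missingness patterns maximizes the observed-data likelihood
(relative log-likelihood tolerance 1e-8, max 2000 iterations,
convergence failure raises with diagnostics). Regression coefficients come
from the estimated moments (b = Σxx⁻¹σxy), standardized by model-implied
variances. SEs: inverse expected (Fisher) information of (μ, vech Σ)
conditional on the realized patterns, delta-mapped to standardized betas,
then rescaled by n/(n − p − 1) with t(n − p − 1) reference — so with
complete data the Wald test is the exact OLS t test. The robust variant is a
sandwich with expected-information bread and analytic per-record score
outer products. Monte-Carlo calibration (500 cohorts at n = 104, MCAR
11–23 %) shows ≈ nominal CI coverage; the raw z-based ML interval
undercovers by ~1–2 points at this n, which motivated the calibration.

MICE uses normal-linear conditionals with posterior draws (scaled
inverse-χ² variance, normal slopes), 10 burn cycles, m = 25 imputations by
default, Rubin's rules with Barnard–Rubin-capped df — chosen over
predictive-mean matching for exact seeded determinism. Listwise is
complete-case OLS on z-scores (statsmodels). Covariate screening maps
variable types to tests (Pearson r, Welch t, χ² contingency) at α = .10,
requiring ≥ 10 complete pairs. Little's MCAR test compares pattern-wise
observed means to EM grand parameters
(χ² = Σ n_p d′Σ_obs⁻¹d, df = Σ k_p − K); it is asymptotically calibrated
but runs conservative at n ≈ 100 where many patterns hold 1–2 cases.
p-values are two-sided with no multiplicity correction, by design.

Design sensitivity inverts the noncentral-F power function for one focal
standardized coefficient among mutually uncorrelated predictors:
f² = β²/(1 − β²), df = (1, n − n_cov − 2), noncentrality f² · df_error. The
df_error convention (rather than f²·n) matches Monte-Carlo power with
sampled regressors to under one point, as the simulation cross-check in the
acceptance script verifies at every run.

## Synthetic-dyad generator

* **Caregiver sequences:** first-order Markov chain over the 8 composite
  states, exponential dwell times (mean 2 s ⇒ ≈150 transitions per 5-min
  session; entropy uses only transition order, so timing only sets sequence
  length). A one-parameter doubly stochastic family interpolating between a
  deterministic cycle (0 bits) and uniform rows (log₂ 7 bits) yields any
  target entropy rate in closed form.
* **IBI series:** AR(1) beat-to-beat jitter (φ = 0.4) plus a respiratory
  sinusoid (0.6 Hz), each calibrated in closed form to contribute half the
  target RMSSD²; planted deceleration epochs add ΔIBI inside their windows.
  Respiratory phase and epoch membership are evaluated on the nominal beat
  grid (cumulative jitter drift ≪ epoch lengths). Target RMSSD 0 produces an
  exactly constant series.
* **EEG:** per-second frequency-domain synthesis with 1/√f amplitudes and
  random phases; theta-bin amplitudes scaled by √gain in attention segments.
  Segment-wise synthesis makes the power modulation exact at the cost of
  1-s boundary discontinuities, which the segmented analysis never sees.
* **Cohort:** linear structural model on standardized latents with planted
  *conditional* coefficients — mean HR enters the HRV equation as an
  exogenous regressor (β = −0.40), so the entropy→HRV coefficient is exactly
  the estimand of the adjusted regression. Defaults mirror the published
  design: n = 104, effects −0.26/−0.24/−0.25/+0.25 (entropy→deceleration/
  theta/HRV, HRV→deceleration), −0.07 entropy→SA, per-variable MCAR rates
  drawn from 0.11–0.23 on the six measured variables (demographics stay
  complete), and descriptive scales matched to the published cohort (e.g.
  entropy 0.79 ± 0.32 bits, RMSSD 11.23 ± 4.65 ms, 64/104 male, gestational
  age 39.21 ± 1.22 weeks clipped to 36–42).

The pipeline re-measures latent values through the full signal chain:
entropy via simulated 5-min event logs, HRV via 300-s IBI recordings,
attention via a 281-s task (onset at 10 s, four 30-s planted deceleration
windows, full looking), theta via gain = max(0.25, 1 + latent/0.01). What
the generator does **not** emulate: MAR/MNAR missingness, infant fussiness
and dropout, ECG waveform morphology, realistic EEG artifact topographies,
negative theta modulation (the multiplicative gain floor compresses
negative latent theta values), or behavioral looking variability (looking
is full-screen-time in synthetic runs). Passing tests therefore demonstrate
estimator correctness and pipeline integrity under the stated statistical
structure, not robustness to every pathology of real infant data.
Measurement noise attenuates planted cohort effects (entropy measured on
150 transitions correlates ≈ 0.88 with its latent value), which is visible
and expected in single-cohort fits.

## Problem sizes used in the tests

Chosen as the package's own validation conditions: entropy-oracle
equivalence on 20 random chains of 10⁴ transitions (tolerance 0.02 bits);
FIML bias/coverage/Little calibration on 500 cohorts of n = 104;
sustained-attention replay on 100 fixtures and 50-seed deceleration
recovery; end-to-end recovery on 100 pipeline runs at n = 500 with planted
entropy→HRV effect −0.25 (EEG/attention stages disabled inside this loop —
the criterion concerns the entropy→HRV path; a separate full-stage run
checks byte-identical determinism). The full suite runs in ~2 minutes on a
single CPU.

## Known limitations

* First-order (k = 1) Markov entropy only; no bias correction for short
  sequences (the plug-in attenuation is documented above).
* The SA algorithm's unspecified details (run counted from first vs fifth
  beat, baseline re-seeding) follow the documented defaults and are
  config-isolated; other choices change phase boundaries by a few beats.
* FIML assumes joint normality; binary sex is handled as a 0/1 regressor,
  which is standard but not literally MVN.
* Little's test is conservative at small n (sparse patterns).
* The MICE implementation is normal-linear only; no PMM, no categorical
  conditionals.
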