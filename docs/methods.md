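# Methods

This note records the models, estimator conventions and numerical choices
behind `icans_qeeg`, and what the synthetic-data tests do and do not show
about real recordings.

## Study design being modelled

Patients receive CAR T-cells on day 0. Routine (≥20 min) 19-channel 10-20
EEGs are taken at a baseline visit 15–20 days pre-infusion and on days +1,
+3, +7 and +14. ICANS, the outcome, is an acute encephalopathy striking
roughly a third of patients, essentially always inside the first two weeks.
EEGs recorded on or after clinical onset are excluded from all risk models:
the question is whether EEG *predicts* neurotoxicity, not whether it
describes it.

## Qualitative grading

The grading scale maps a finite descriptor space to grades 0–3. Each rule is
a predicate on one or two descriptors with an attached grade; a form's grade
is the **maximum over triggered rules** — the clinical convention that the
worst finding drives severity, and the reading that makes the scale total
and monotone. Choices made where the scale's tabular definition leaves rows
open:

* "normal PBF" means alpha *or* beta predominant background.
* High-prevalence theta over a normal background maps to grade 2 (it is
  listed under the grade-2 column of the scale's theta row); with a theta or
  delta background the background rule already dominates.
* Delta prevalence covers polymorphic and rhythmic delta alike; the
  morphology is recorded but carries no grading weight.
* Descriptors with no rule attached (symmetry, PDR, continuity, voltage,
  ictal-interictal-continuum flag) never change the grade. They are kept on
  the form because raters record them.

Monotonicity (worsening any single descriptor never lowers the grade) and
totality are verified by exhaustive enumeration of the grade-relevant
descriptor space (1536 combinations) in the test suite. Dual-rater
adjudication is a human process and out of scope; the package computes
unweighted Cohen's κ between two grade lists and leaves disagreement
resolution to the raters.

## Preprocessing

* **Units/time**: signals in µV; intervals half-open `[onset, onset+dur)`
  seconds from record start.
* **Powerline comb**: the line frequency (default 50 Hz) and every harmonic
  below Nyquist are removed by whole-record least-squares regression on
  sine/cosine pairs. For a stationary line component this is exact and
  phase-preserving. A recursive (IIR) notch cascade was tried first and
  rejected: its forward-backward edge transients on 20 s records leave
  percent-level residuals that dominate the stopband spec, and they corrupt
  the phase estimates feeding transfer entropy.
* **Band-pass**: 0.5–40 Hz, realized by applying the squared magnitude
  response |H(f)|² of an order-4 Butterworth design directly on the DFT —
  the exact zero-phase analogue of forward-backward filtering, without its
  start-up transients. The cost, circular wrap-around leakage, is negligible
  for multi-minute records. Consequences verified in tests: a pure line tone
  is attenuated below 1% RMS, passband tones preserved within 0.01%, DC
  exactly removed, and re-filtering passband content changes RMS by <1%.
* **Epoch assembly**: annotated artifact intervals (annotation is manual /
  upstream; automated detection is a non-goal) are excised and the clean
  segments concatenated in order with no tapering or resampling. Records
  with under 20 s of clean signal are *rejected* (a return value, not an
  exception, because rejection is an expected cohort event). Windows may
  span excision seams; the per-window Hann taper bounds the leakage a seam
  can inject.
* **Windows**: T = 2.0 s, Δt = 0.25 s; count = floor((L−T)/Δt)+1.

## Quantitative features

* **PSD** per window/channel: Hann-tapered periodogram, density scaling, so
  the PSD integral matches the window variance (Parseval; within 1%).
* **Band energies**: trapezoidal PSD integral over closed bands δ=[2,4],
  θ=[4,8], α=[8,14], β=[14,30] Hz, edges interpolated onto the grid.
  DTAR = (E_δ+E_θ)/E_α, defined only for positive alpha energy.
* **Amplitude entropy** H: histogram differential entropy (nats) of the
  sample distribution, Freedman–Diaconis bin width. Shift-invariant and
  obeys H(aX)=H(X)+ln a; a constant window returns −∞ with a degeneracy
  warning. The estimator choice is a design decision — "signal complexity in
  amplitude terms" admits several estimators; the amplitude histogram was
  chosen because phase structure is separately captured by PTE.
* **Higuchi fractal dimension** F with kmax = 10 (conventional for 2 s
  windows at routine sampling rates; configurable): least-squares slope of
  log L(k) vs log k over the standard normalized curve lengths. F is clipped
  to [1,2] with a warning — white noise legitimately estimates a hair above
  2. Validated against the closed-form limits (smooth curve → 1, white noise
  → 2) and a literal brute-force reimplementation.
* **Record summary**: the median over all (window, channel) pairs jointly —
  one scalar per feature per record. Channel-wise-then-window-wise
  aggregation would weight channels equally regardless of window count; the
  pooled median was chosen and is order-invariant in tests.
* **Baseline normalization**: post-infusion features divided by the
  patient's baseline values (ratio rather than difference: scale-free, hence
  comparable across patients whose absolute amplitudes differ). Requires
  strictly positive baseline features; violations raise an error naming the
  offending feature.

## Connectivity

PTE(x→y) is the transfer entropy between binned instantaneous phases
(analytic signal of the broadband 0.5–40 Hz channel — broadband by design,
avoiding band-selection bias):

PTE(x→y) = Σ p(y_{t+δ}, y_t, x_t) · log [ p(y_{t+δ}|y_t,x_t) / p(y_{t+δ}|y_t) ]

Estimator conventions (standard in the PTE literature, all configurable):
prediction delay δ = series length / total phase sign changes of the two
channels; bin count = round(exp(0.626 + 0.4·ln(N−δ−1))). PTE is computed on
the **full assembled epoch**, not per 2 s window — a 512-sample window
cannot populate a triple phase histogram. Estimator bias is nonzero but
direction-symmetric for independent channels (verified against a permutation
null); directed couplings are detected via the PTE asymmetry of a pair.

Graph layer: edge weight = PTE; path-based measures (betweenness,
eccentricity, diameter) use edge length 1/weight so stronger coupling means
shorter distance; no edge thresholding (avoids a free parameter).
Eigenvector centrality is the Perron eigenvector of the transposed weight
matrix (centrality accrues over in-edges), normalized to unit maximum; among
eigenvalues tied in magnitude the one with largest real part is taken,
which for a non-negative matrix is the Perron root. Eccentricity and
diameter are flagged infinite (not raised) off strong connectivity.

## Survival models

* Counting-process rows `(start, stop]` partition (0, event-or-censor day]
  per patient; the covariate is carried forward from the most recent usable
  EEG (the baseline value applies from day 0 until the first post-infusion
  EEG). An event on day 0 occupies a nominal (0, 0.001] interval so it
  contributes a positive at-risk time.
* Fits use the Cox partial likelihood with Efron tie handling (daily
  onset resolution makes ties common) and Wald 95% CIs; the fixed model and
  the time-dependent model are fitted by separate engines and agree to 1e-6
  on constant covariates (a cross-check, also against a brute-force
  partial-likelihood maximization in the tests).
* Stepwise selection: forward entry by likelihood-ratio test at α = 0.05
  with a backward check after each entry; lexicographic tie-break makes the
  procedure deterministic. The null-model log-likelihood is recovered from
  any single-covariate fit via its LR statistic.
* Tertile analysis: empirical 33.3/66.7 percentiles (linear interpolation —
  a documented convention, configurable through the percentile source), risk
  dichotomized at the upper cut-off. Heavy ties trigger a degeneracy
  warning.
* No multiplicity correction is applied across the feature family; reports
  should say so.
* Censoring for non-events defaults to day 30 (configurable); competing
  risks (early non-neurological deaths) are treated as censoring, a known
  simplification.

## Synthetic-data generator

What it emulates: band-structured multichannel EEG (per-channel sinusoidal
oscillators at random frequencies inside each clinical band, 1/f background
noise by spectral shaping of white noise), lagged scaled inter-channel
coupling, annotated 0.5–3 s high-amplitude artifact bursts covering a
requested fraction of the record, the fixed EEG schedule (baseline day
uniform in [−20, −15], post days +1/+3/+7/+14), and ICANS onsets from a
piecewise-exponential proportional-hazards model whose covariates update at
EEG days.

The coherence device is a latent per-patient *slowing* severity s(t):
it enters the hazard log-linearly (β = 0.8 per unit by default), sets the
grade (floor of s, clipped to 0–3) and hence the sampled evaluation form,
and sets the oscillator amplitudes monotonically (theta rises, alpha falls
with s) and thereby the parametric band energies attached to each EEG
(oscillator energy A²/2 plus a noise floor, with multiplicative log-normal
measurement noise). Qualitative and quantitative arms therefore agree by
construction, which is exactly what the integration tests need: an injected
direction of effect that both arms should recover.

Default conditions reproduce the modelled study: baseline grade mix 60:6:2
(grades 0:1:2) per 68 patients; hazard confined to a 15-day acute risk
window with baseline rate 0.013/day, giving ≈32–33% incidence and onsets in
days 0–15 (mean ≈7); administrative censoring at day 30. The log-linear
covariate-hazard link is an assumption for testing, not a claim about ICANS
biology.

What it does **not** emulate — hence what passing tests do not show about
real data: realistic artifact morphology (eye blinks, EMG), volume
conduction and reference effects, non-stationary background dynamics,
anaesthetic states, or the true functional form linking EEG slowing to
ICANS hazard. Tests on this generator validate the *machinery* (estimators,
expansion, fits) and directions of effect, not clinical effect sizes.

EDF output comes from a minimal in-package 16-bit EDF writer (1 s data
records, per-channel physical range from the data; integer sampling rates
only); reading goes through MNE, which doubles as an independent round-trip
check of the writer.

## Problem sizes in tests and drivers

The test suite runs the full chain at sizes chosen to make its statistical
assertions sharp but cheap: 1000 2-second windows for spectral/entropy
means, 100 seeds for PTE directionality, 100 random digraphs for the graph
oracle, 200 replicate cohorts of n = 1000 for hazard-ratio recovery and CI
coverage, and one n = 1000 cohort for the integrated direction-of-effect
check. The analysis drivers use a 68-patient cohort (the modelled study
size) for the descriptive stages and n = 1000 for the risk stage.

## Known limitations

* The grading completion for descriptor combinations the scale's table does
  not explicitly pin down is documented above, not asserted as the original
  raters' intent.
* PTE bin-count/delay heuristics and per-epoch (not per-window) computation
  are conventions; different choices change absolute PTE values (not,
  empirically, null-asymmetry behaviour).
* The amplitude-entropy estimator and the ratio form of baseline
  normalization are documented choices among reasonable alternatives.
* Real-cohort hazard ratios are not reproducible from synthetic data by
  design; the pipeline reproduces directions of effect only.
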