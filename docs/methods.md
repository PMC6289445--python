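# Methods

This note records the scientific and numerical choices behind `fnirsvmd`:
the signal model, the synthetic-data generator and what it does and does
not emulate, the estimators, and the calibration experiments that the test
suite and `scripts/acceptance.py` run.

## Experimental design

A session is parameterized by `SessionDesign`: baseline 60 s, then
`trials_per_valence` trials per valence (default 5 + 5) of a 15 s stimulus
and 30 s rest, at 1.81 Hz.  Valence order is a seeded uniform permutation
of the trial multiset — nothing constrains runs of equal valence, since the
design only calls for "random order".  Durations are discretized with a
ceiling (35 s × 1.81 Hz = 63.35 → 64 samples), onsets with a floor
(60 s × 1.81 Hz = 108.6 → index 108), and epochs are half-open
`[start, start + N)` windows.  The ceiling convention is what makes the
reference epoch exactly N = 64 samples; it is applied everywhere a duration
becomes a sample count.

## Optical conversion

`mbll_convert` solves the conventional modified Beer–Lambert system
ΔA(λᵢ) = l·d(λᵢ)·Σ_X α_X(λᵢ)ΔC_X per sample.  Default extinction
coefficients at 760/830 nm (and a default DPF of 6, emitter–detector
distance 30 mm) ship in `fnirsvmd/data/extinction_760_830.json` and are
overridable — they are tabulated compendium values, not constants of the
method.  The matrix orientation follows the forward model (it round-trips
with `forward_optical_density` to machine precision); the transposed
orientation sometimes seen in print is treated as a typesetting variant.
A condition number above 1e8 raises, naming the wavelengths.  The DPF may
be a scalar or a per-wavelength pair.

## Synthetic recordings

`simulate_session` builds ΔHbO per channel as

    activation + cardiac + respiratory + Mayer + drift + white noise

where the activation component is the session-level expected-response
regressor of each event scaled by that channel's β (µM) for the event's
valence, with the regressor normalized so an isolated event peaks at 1 —
hence β is the per-event response amplitude in µM.  ΔHbR is −0.3 × the
HbO activation component plus independently drawn noise scaled by the same
ratio (the analysis classifies HbO only, so HbR needs only plausibility).

Noise defaults (per channel; sinusoid phases drawn uniformly per channel
per session, so there is no artificial cross-channel coherence):

| term        | frequency | amplitude |
|-------------|-----------|-----------|
| cardiac     | 1.1 Hz    | 0.4 µM    |
| respiratory | 0.25 Hz   | 0.6 µM    |
| Mayer waves | 0.1 Hz    | 0.8 µM    |
| drift       | —         | 0.005 µM/s|
| white noise | —         | SD 0.8 µM |

The study these conditions emulate reports no SNR or amplitude figures, so
the defaults are calibration choices: they put single-trial t-values for
β = 1 µM in the neighbourhood of the activation threshold, making ROI
selection genuinely uncertain at trial level.  `NoiseModel.white_only()`
(i.i.d. Gaussian only) and `NoiseModel.silent()` give the reduced
configurations used by the calibration experiments below.

What the generator does **not** emulate: optode geometry and photon
transport, motion artifacts, serially correlated (1/f) instrumental noise,
inter-subject anatomical variability, or habituation across trials.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis* under its own assumptions, not performance on real recordings.

`make_cohort` draws per-subject, per-session β from a `BetaSampler`
(independent normals per channel and valence; a point-mass sampler yields
identical subjects).  Note that independently drawn positive/negative β
constitute a *real* per-subject class difference even when the two means
are equal — a null cohort must share the realized β across conditions
(point mass), not merely the distribution.

## Preprocessing

Order: low-pass → detrend → baseline-correct → epoch.  Filtering is
zero-phase (forward–backward) 4th-order Butterworth at 0.15 Hz; epoch-locked
analyses need no group delay, and the price is a squared magnitude response
(−6 dB rather than −3 dB at the cutoff).  Detrending is linear least
squares over the session by default, with an optional discrete-cosine basis
(`basis="dct"`, cutoff period 128 s) for users wanting SPM-style drift
removal.  Baseline correction subtracts the per-channel mean of the first
60 s; whether the original study did this by subtraction or inside its
detrending software is unknowable from the text, so subtraction is the
documented choice here.  detrend → baseline-correct is an exact projection
(idempotent to numerical precision); refiltering is *not* exactly
idempotent — an IIR magnitude response attenuates transition-band content
on every pass, which the tests bound rather than deny.

## Activation mapping

The expected response X_r is the canonical double-gamma impulse response
(peak delay 6 s, undershoot delay 16 s, undershoot ratio 1/6 — all
configurable) convolved with the stimulus boxcar and peak-normalized.  With
these canonical parameters the net impulse response crosses zero near 12 s,
so the 15 s-boxcar regressor peaks at ≈11.6 s after onset, i.e. *before*
stimulus offset — the undershoot truncates the plateau.

`RobustGLM` fits y = β·x + α by IRLS with Tukey bisquare weights
(c = 4.685, 95% Gaussian efficiency), rescaling residuals each iteration by
MAD/0.6745, converging when coefficients move less than 1e-8 (cap 50
iterations; non-convergence is flagged and the last iterate returned).  The
standard error uses the final-iteration robust covariance with the standard
small-sample correction (the H1 form).  Two conventions to note:

- **Degrees of freedom** are N − 1 = 63 by default, honouring the reference
  analysis's explicit statement, even though a two-regressor model
  conventionally uses N − 2 (`dof="n_minus_2"` is available; at N = 64 the
  thresholds differ in the third decimal).
- **MAD constant** is 0.6745 exactly (the MATLAB-style convention), not
  Φ⁻¹(3/4) ≈ 0.67449; cross-checks against statsmodels' RLM agree to ≈1e-5
  once this is accounted for.

Activation is one-tailed: a channel is active when t > t_crt(63, 0.05) =
1.6694 ("1.67"), strictly.  `fit_condition` offers two map styles: per-trial
(fit each epoch, average β, SE and t over trials — the default, matching
trial-averaged map captions) and averaged (average the epochs, fit once).
They coincide for a single epoch.  An empty ROI is legal and warned about;
the cohort pipeline then falls back to the single highest-t channel so that
ROI-averaged feature extraction stays defined.

## Features and classification

Features are computed on the first 20 s (37 samples) of the ROI-averaged
HbO epoch: mean, peak, unbiased variance, skewness (third standardized
moment), kurtosis in the Pearson convention (normal → 3; `"excess"`
available), the robust-GLM t-value with X_r restricted to the window, and
the least-squares slope against time in seconds.  Constant input returns
zero spread moments by convention but raises on the t-value — a constant
epoch indicates an upstream fault, not a value.  Min-max rescaling to
[0, 1] is applied per feature column within one classification problem
(one subject, one store), before cross-validation splitting, matching the
reference description; a constant column rescales to zeros with a warning.
Rescaling within-subject rather than across the cohort is a choice the
source leaves open.

`LinearDiscriminant` is classical pooled-covariance LDA with configurable
priors, a trace-scaled ridge (λ = 1e-6·tr(Σ)/p) when the pooled covariance
is singular, and ties broken deterministically toward the first label in
sort order.  `cross_validate` defaults to leave-one-out with **uniform
priors**: the design is balanced, and re-estimating priors inside
leave-one-out folds (4-vs-5 training sets) would bias null accuracy below
chance through fold-induced imbalance.  `lda_fit` keeps empirical priors as
its default for full-data fits, where balance makes the two coincide.
Stratified k-fold is available; the fold count must not exceed the smallest
class.  The validation protocol of the original study is unreported; no
attempt is made to reverse-engineer its printed denominators.

`pair_search` evaluates all 21 unordered pairs of the 7 features in
lexicographic order; `cohort_pair_search` aggregates subject-wise grids as
mean ± SD and selects the best pair by aggregate mean.

## Reporting

Accuracies aggregate as arithmetic mean and sample SD (n − 1).  The
one-sample test against chance is t = (mean − chance)/(SD/√n) with n − 1
degrees of freedom, two-tailed by default (the source does not state the
tail; one-tailed is available).  Display rounding is 2 decimals for
accuracies, 4 for t; significance marks are * (p < 0.05) and ** (p < 0.01),
with very small p-values floored to "0.00" in display only.
`fnirsvmd.datasets` ships a published 20-subject accuracy table for
demonstrating these utilities; one of its printed column means (67.04)
disagrees with its own column (which averages to 68.05 while matching the
printed SD) — the discrepancy is preserved as printed.

## Calibration experiments

`fnirsvmd.validation` backs both the acceptance tests and
`scripts/acceptance.py`.  Problem sizes are fixed so the whole suite runs
in well under a minute on one CPU while keeping Monte-Carlo error small
against the bands checked.

- **MBLL round trip** — forward OD then inversion on random concentrations;
  error at machine precision (≤1e-10 required).
- **OLS equivalence / outlier resistance** — unit-weight robust fit equals
  a direct least-squares solve to 1e-10; with 10% of samples spiked by
  +50 µM the bisquare estimate lands closer to truth than OLS in ≥95 of
  100 replicates.
- **Null calibration** — 2,000 (5,000 in the script) β = 0 epochs of
  i.i.d. Gaussian noise: the rate of t > t_crt stays inside the 99%
  binomial band of 0.05 (measured long-run rate ≈0.0496 at 20,000 epochs).
  White noise is the appropriate null here: the binomial band presumes
  independent draws, which coherent physiological oscillations are not.
- **β recovery** — 4 sessions × 2 valences × 16 channels with β drawn in
  [0.5, 2] µM, trial-averaged fits on raw epochs under i.i.d. noise at the
  default SD: true β within β̂ ± 3 SE for ≥95% of channels.  This is run
  without the low-pass/oscillation stages deliberately: the GLM carries no
  serial-correlation correction (prewhitening is out of scope), and
  filtered or oscillation-contaminated residuals violate the independence
  its standard errors assume — measured coverage drops to ≈85% there.  The
  check certifies the estimator's calibration in the regime where its
  assumptions hold.
- **End-to-end discrimination** — a cohort with well-separated valence
  activations (1.8 vs 0.4 µM, full structured noise) yields best-pair
  leave-one-out accuracy >90%.  Chance-level checks train on label-shuffled
  features of an identical-β (point-mass) cohort and score an independent
  held-out session with a pre-specified feature pair: out-of-sample
  predictions are then independent of the true labels, so pooled accuracy
  is binomial around 50% (two-class) or 25% (four-class), verified against
  99% bands.  Leave-one-out itself is *not* used for the null: on 10
  permuted trials its folds are strongly correlated and its accuracy has
  super-binomial variance (measured ≈1.4× the binomial SD), and selecting
  the best of 21 pairs would bias any null upward.

## Known limitations

- No motion-artifact handling, short-separation regression, prewhitening,
  or scalp interpolation of maps (a 4×4 channel-grid heatmap stands in).
- HbR is generated and converted but never analyzed, mirroring the
  reference analysis.
- Classification beyond feature pairs (triplets, nonlinear classifiers,
  cross-subject transfer) is out of scope.
- The generator's amplitudes are calibration choices; absolute accuracy
  figures on synthetic cohorts are not predictions of human-study results.
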