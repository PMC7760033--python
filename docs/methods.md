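# Methods

This note records the scientific and numerical choices behind `nmrfinger`:
what each stage assumes, which parameters matter and why their defaults are
what they are, what the synthetic cohorts do and do not emulate, and the
known limitations.

## Problem setting

The package implements a serum ¹H-NMR fingerprinting analysis for
stratifying NSCLC patients by their response to anti-PD-1 checkpoint
inhibitors. One pre-treatment spectrum per subject is reduced to a vector of
normalized spectral areas over fixed chemical-shift bins; a supervised
two-class latent-variable model is then cross-validated to ask whether that
fingerprint predicts the clinical outcome, and individual metabolite windows
are tested univariately. Clinical outcome labels are derived from ordered
iRECIST radiological-assessment sequences rather than from a single scan,
because immunotherapy responses can pseudo-progress: an early apparent
progression driven by immune infiltration that a first-assessment rule
misreads as failure.

## Spectral processing

* **Apodization / FT.** Raw FIDs are multiplied by `exp(-pi * lb * t)` with
  `lb = 0.3` Hz by default (a 0.3 Hz Lorentzian line broadening) before the
  discrete Fourier transform. The first FID point is halved so that a pure
  exponential decay transforms to a flat-baseline Lorentzian. Zero-order
  phasing maximizes real-part positivity on a 1-degree grid; baseline
  correction subtracts a low-order polynomial fitted to signal-free regions
  (defaults 9–10 ppm and below 0.1 ppm). File-based spectra are assumed
  already phased and baseline-corrected, the normal situation when spectra
  come out of vendor processing.
* **Calibration.** The chemical-shift axis is anchored on the anomeric
  α-glucose doublet at δ 5.24 ppm: the midpoint of the two most prominent
  local maxima in a 5.15–5.35 ppm search window (single maximum if only one
  is found or the two are farther apart than 0.03 ppm, i.e. not one
  doublet). Peaks must exceed a prominence of 0.1 × the window's dynamic
  range; otherwise the subject fails calibration, is reported by name, and
  the batch continues without it. Serum always contains glucose, which is
  why this anchor is usable without adding a reference compound.
* **Binning.** The 10.00–0.2 ppm region is segmented into 0.02 ppm bins
  anchored at 10.00 ppm and descending — 490 bins. Each bin value is the
  trapezoidal integral of intensity over the bin's ppm interval, computed as
  differences of the cumulative trapezoid interpolated at the edges, so bin
  boundaries falling between grid points are handled exactly in the
  piecewise-linear sense. Bins are left-closed/right-open on the descending
  axis; a point on an edge belongs to the higher-ppm bin.
* **Normalization.** Bins whose open interval overlaps the open water
  interval (4.50, 5.00) ppm are removed entirely — 25 bins, leaving 465 —
  and each subject's row is divided by its remaining total area, so rows sum
  to exactly 1. Removing the water bins from the matrix (not merely from the
  normalization denominator) is the common fingerprinting convention; a
  config switch is deliberately *not* offered for partial behaviour because
  a residual-water bin carries suppression artefacts, not biology. The
  normalized fingerprint is invariant under any per-subject global intensity
  rescaling (receiver gain, dilution), which is the point of the step.

## The classifier

OPLS-DA with a single predictive component and `n_orthogonal` (default 1,
0–5 supported) orthogonal components, fitted exactly as documented in
`nmrfinger.chemometrics`. With zero orthogonal components the model is
provably one-component PLS; the test suite checks equivalence against an
independent NIPALS implementation at 1e−10.

* **Scaling default: unit variance.** Centring-only, unit-variance and
  Pareto scaling are all available. The default is unit variance because of
  a structural property of serum fingerprints: the glucose resonances carry
  by far the largest absolute between-subject variance, so a
  covariance-based PLS weight (centring only) is dominated by glucose bins
  and a genuine but low-concentration discriminator (here alanine and
  pyruvate, an order of magnitude below glucose) contributes almost nothing
  to the predictive direction. On synthetic cohorts with planted effects the
  centring-only model stays near chance while the univariate test flags the
  same metabolites at p ≈ 1e−8; unit-variance scaling gives every bin equal
  a-priori leverage and recovers the signal. The cost of unit-variance
  scaling — inflation of noise-only variables — is visible in the test suite
  itself: the raw-feature Gaussian-blob toys are tested with centring-only
  scaling for exactly that reason.
* **Class coding and threshold.** Responder = +1, non-responder = −1,
  decision threshold 0 on the coded scale; the predictive direction is
  sign-fixed so responders score positive. Class imbalance is not
  re-weighted. A subject equal to the training mean scores exactly 0.
* **Degenerate fits.** If the orthogonal step absorbs all class-correlated
  variance, or `n_orthogonal >= rank(X)`, the fit aborts with a message
  advising fewer orthogonal components rather than returning a silent
  near-zero model.

## Validation

* **LOO CV** refits everything — centring, scaling, orthogonal filter —
  inside each fold; out-of-fold scores are pooled for accuracy, DQ² and
  AUC.
* **Monte Carlo CV** uses stratified random 90/10 splits (500 repetitions
  by default). Stratification is necessary at n ≈ 34: an unstratified 10%
  test draw frequently contains one class only, which would make accuracy
  undefined per repetition. Overall accuracy is the mean of per-repetition
  accuracies; DQ²/AUC use predictions pooled over all test appearances.
* **Permutation test.** The statistic is the full cross-validated accuracy,
  recomputed per label permutation with the same CV scheme as the observed
  run; p = (1 + #{perm ≥ observed}) / (B + 1) (add-one estimator, never 0).
  B defaults to 500. The seeded simulation suites use B = 99, which bounds
  p from below at 0.01 — granular enough for every check made there — and
  keeps each 20-seed sweep around a minute.
* **DQ².** Residuals of predictions beyond their own class label are zeroed
  before 1 − PRESS/TSS, so DQ² ≥ Q² always, with equality iff nothing
  overshoots. Reported to 2 decimals; accuracies to whole percent.
* **AUC** by the rank (Mann–Whitney) formula with half-credit ties;
  constant score vectors return 0.5 with a warning rather than failing.

## Synthetic cohorts

The generator exists so every stage runs, and is tested, with no external
data. It emulates the *signal-level* structure of processed serum spectra:

* six metabolites (glucose, lactate, alanine, pyruvate, citrate, glycine)
  as sums of unit-area Lorentzian lines at textbook chemical shifts,
  linewidth 1.5 Hz FWHM at 600.13 MHz; line amplitudes proportional to
  proton counts; doublets split by their J-couplings;
* base concentrations in serum-like proportions (glucose 5, lactate 1.5,
  alanine 0.4, glycine 0.25, pyruvate 0.1, citrate 0.1 a.u.) — the point is
  the order-of-magnitude hierarchy (glucose dominates the fingerprint), not
  absolute units;
* between-subject biology as independent per-metabolite log-normal
  variation, default CV 0.15; the planted class effect multiplies responder
  concentrations (default 0.6× alanine and pyruvate, i.e. lower in
  responders — the direction reported for anti-PD-1 response in serum; no
  published effect magnitude exists, so 0.6 is a package choice sized like
  a clearly real but not trivial metabolic difference);
* per-line chemical-shift jitter (SD 0.001 ppm), a smooth two-hump
  macromolecule-like baseline, and additive Gaussian noise (SD 0.002 on
  peak heights of order 10–100) — the regimes binning, calibration and
  normalization are meant to absorb;
* clinical records drawn per class: responders get ≥3 radiological
  assessments and log-normal TTF/OS with medians 54/75 weeks,
  non-responders ≤2 assessments and medians 10/19 weeks, so generated
  labels round-trip exactly through the second-assessment rule.

Not emulated: lipoprotein envelopes, J-coupling evolution and strong-
coupling rooflines, relaxation editing, field- or pH-dependent shift
changes, and correlated metabolite physiology (each metabolite varies
independently). Consequently, passing tests show the pipeline's statistics
behave correctly under a controlled generative model — chance-level results
on effect-free cohorts, calibrated permutation p-values, recovery of
planted effects — not that real sera of any given cohort are separable.

## Clinical endpoints

Two labelling rules: first-assessment (responder iff the first iRECIST code
is iCR/iPR/iSD; death before assessment is non-response) and
second-assessment (responder iff therapy continued to a third or later
assessment). Composite printed codes such as "iSD/PR" count by their more
favourable component; bare "HP", "na (HP)" and "iPD" are accepted as
synonyms of their iRECIST counterparts, since printed tables use them
loosely. For medians and rank-sum comparisons, censored ("+", ongoing/alive)
times enter at their recorded week — the convention that reproduces the
published cohort medians — and a Kaplan–Meier median honouring the censor
flags is offered alongside, clearly separated, for survival-style reporting.
On the transcribed nivolumab table the strict first-assessment count is 8
responders; the published text says 9. The package reports the computed
count and does not force agreement (the "iSD/PR" entry and transcription
ambiguity make the printed 9 unrecoverable). Likewise the plain median OS of
the 19 transcribed non-responders is 19 weeks against a printed 19.5; both
conventions are computable from the API and neither is asserted as correct.

## Univariate stage

Metabolite levels are integrals of the normalized fingerprint over
configurable ppm windows (fractional bin overlap at window edges); the
shipped windows mirror the generator's resolved peaks so simulation and
quantification stay self-consistent. Groups are compared with the two-sided
Wilcoxon–Mann–Whitney test — exact null distribution when min(n) ≤ 20 and
the pooled sample has no ties, normal approximation with continuity and tie
correction otherwise — and Benjamini–Hochberg step-up FDR. The significance
call requires raw p < 0.05 *and* FDR < 0.05.

## Problem sizes used in the checks

The seeded end-to-end suites use cohorts at the study's scale: 20 seeds of
n = 34 (15/19) effect-free cohorts for null calibration and 20 seeds of
17 + 17 with the default planted effect for recovery, each with LOO CV and
B = 99 permutations; spectra are rendered on a 16384-point axis over
10.5 to −0.5 ppm (0.4 Hz per point, ~3 points per linewidth). The whole
suite runs in a few minutes on one core.

## Known limitations

* Single predictive component only; multi-class discrimination, kernel
  variants and VIP-style variable importance are out of scope (metabolite-
  level inference goes through the univariate stage).
* Calibration is a single global shift per spectrum; it cannot fix
  differential peak movement (no icoshift-style segment alignment).
* The Monte Carlo permutation path re-runs the full repeated-split CV per
  permutation; with the default 500 × 500 this is expensive and is the
  price of a statistic that matches the observed one exactly.
* `BinnedMatrix.from_csv` trusts its header metadata; files edited by hand
  can mislabel normalization state.
* Survival handling is deliberately simple (rank tests on censor-as-
  observed times plus KM medians); no Cox or multivariable modelling.
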