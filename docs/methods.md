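# Methods

## The spectral model

A plasma CPMG spectrum is rendered as a sum of Lorentzian multiplets on a
uniform ppm axis (default 0–9 ppm, 8192 points, 700 MHz observe frequency):
each resonance contributes `concentration × proton_weight` of integrated
area, split over its multiplet lines, with a half-width of
`linewidth / (2 × observe_frequency)` ppm. Lineshapes are purely Lorentzian —
the natural shape of exponentially decaying spin-echo signals, and the one
with a closed-form integral, which the tests exploit. Broad lipoprotein
side-chain envelopes (-CH₃ 0.875, (-CH₂-)ₙ 1.29, βCH₂ 1.57, allylic 2.02,
olefinic 5.33 ppm) are single wide Lorentzians (10–12 Hz); small metabolites
use literature chemical shifts shipped as an editable YAML file
(`src/ucnmr/data/metabolite_library.yml`). These shifts are defaults, not
ground truth for any particular spectrometer or pH.

Resonances that carry a bucket annotation are modelled as *unresolved*
single Lorentzians placed mid-bucket. The alternative — resolved multiplets
whose outer lines sit on 0.02-ppm bucket edges — makes the in-bucket
integral a steep function of chemical-shift jitter (a 0.002-ppm shift can
move half a line across the edge), which destroys the one-bucket-per-
metabolite percent-difference readout the analysis relies on. Multiplet
structure is retained where it is informative rather than fragile: the
lactate reference doublet at 1.33 ppm (its two lines are what the
referencing step centroids), the isoleucine 0.94 triplet, and the aromatic
doublets/triplets of tyrosine and phenylalanine away from their annotated
buckets.

Interferences at the four headline buckets (myo-inositol 4.05, (-CH₂-)ₙ
1.29, isoleucine 1.01, glucose anomeric 5.23 ppm) are kept below ~5% of the
in-bucket area under the default concentrations, so a configured
concentration change is recovered as a bucket-integral change to within
≈1.5 percentage points in the noise-free limit; the remainder is genuine
spectral overlap (e.g. the olefinic envelope shoulder under the anomeric
glucose bucket), which is also why bucket fold changes and concentration
fold changes are not identical in real spectra.

### FIDs

`spectrum_to_fid` inverts the rendered spectrum into a *causal* complex FID
via the discrete analytic-signal construction (negative-time half of the
two-sided inverse FFT zeroed, interior points doubled). A real absorption
spectrum corresponds to a causal decaying signal; with this construction
the real part of the Fourier transform equals the input spectrum exactly,
`process_fid(spectrum_to_fid(s))` is an identity on the original grid at
zero line broadening, and zero-filling is well defined. Feeding the
two-sided inverse FFT into a zero-filling pipeline instead silently
truncates the negative-time content and corrupts lineshapes.

## Cohort structure

Class labels are generated first; clinical scores are drawn consistently
with the labels afterwards, which keeps the configured contrasts exact.
Subject concentrations are `baseline × effect multiplier × log-normal
factor`, the log-normal having mean 1 and CV `between_subject_cv`
(default 0.15 — mid-range for plasma metabolites). Defaults: additive
Gaussian noise SD 5 (peak heights are of order 10³, i.e. SNR in the
hundreds, typical of plasma CPMG), per-resonance jitter SD 0.002 ppm,
per-sample global shift SD 0.003 ppm (undone by lactate referencing),
baseline drift amplitude 20 on a random cubic.

The longitudinal simulator assigns 24 low / 16 high baseline endoscopic
classes and an 18 improved / 15 worsened / 7 no-change outcome split,
composes the endoscopic-activity effect (by each sample's own class) with
the prognostic effect (baseline samples, by outcome; no-change subjects get
the square root of the prognostic multiplier, placing them midway between
the outcome classes in log space), shares one biological factor per subject
across timepoints, and draws Nancy grades that track the endoscopic class
imperfectly (~25% fall in the excluded grade 2, ~10% cross over). SCCAI,
blood parameters and medication flags are label-independent by design, so
the independence screens have true-null structure: passing them shows the
screens are calibrated, not that real clinical chemistry is uninformative.

## Pre-processing choices

- Zero-fill factor 2, 0.30 Hz exponential line broadening.
- Zero-order phase chosen analytically to maximize summed real intensity;
  adequate for simulated data, standing in for manual vendor phasing.
- Baseline: 3rd-degree polynomial by iterative asymmetric reweighting —
  points more than 3 noise-SDs (estimated from negative residuals) above
  the fit are masked and the fit repeated until the mask stabilizes. This
  tracks the centre of the noise rather than its lower envelope.
- Referencing: intensity-weighted centroid of the above-half-maximum region
  (smooth weighting; a hard 50% cut adds an O(grid-spacing) asymmetry)
  within 1.33 ± 0.05 ppm, rejected if no point clears a robust
  median + 5·MAD threshold.
- Buckets are half-open `[left, left + 0.02)` with left edges at
  0.08 + k·0.02 and 5.20 + k·0.02, integrated by trapezoid on the native
  grid with interpolated edge values; the absolute value is applied to the
  bucket integral (not per point). 206 + 165 = 371 buckets; the 4.20–5.20
  ppm water region yields none.
- Pareto scaling mean-centres and divides by √SD (sample SD, n−1);
  constant buckets map to zero and are flagged. `apply_scaling` uses only
  the fitted means/divisors, never the new rows.

## O-PLS-DA

Univariate-response NIPALS: `w ∝ Xᵀy` (unit norm, invariant under
orthogonal deflation), orthogonal components extracted from the part of the
loading orthogonal to `w` and deflated out, final predictive component from
the deflated matrix. With zero orthogonal components the model is exactly a
one-component PLS1 regression (asserted against scikit-learn's
implementation in the tests). The response is encoded 0/1; the decision
threshold is the midpoint of the training class-mean predictions, which is
robust to class imbalance and equals 0.5 for balanced training sets;
borderline calls are predictions within 0.1 of the threshold.

The number of orthogonal components is chosen by internal stratified 7-fold
CV (fold count reduced with a warning if a class is smaller): components
are added while Q²Y improves by more than 0.01 absolute, capped at 9, with
Q² = 1 − PRESS/TSS and TSS about the training-fold response mean.

VIP over the single predictive component reduces to `√p · |w|`
(mean-square 1). A bucket counts as a significant discriminator when its
VIP exceeds 1, its correlation loading (Pearson r between the scaled bucket
and the predictive score) is extreme at the two-sided 5% level against a
500-draw label-permutation null (each draw refits the predictive
direction), and the sign of its unscaled between-group percent difference
agrees with the loading. The permutation null — rather than a bootstrap
interval of the in-sample correlation — is what keeps the rule calibrated:
the predictive score is itself fitted to the labels, so in-sample
correlation loadings are inflated under the null and resampling intervals
around them rarely cover zero (measured ~22% false selection versus ~5%
with the permutation band).

## Ensemble validation

Per repetition: the majority class is randomly undersampled to the minority
size (the correction for unequal class sizes; it also makes sensitivity and
specificity comparable), the balanced set is split into stratified external
folds (default 10, reduced with a warning for small classes), the Pareto
scaler and the O-PLS-DA model are fitted inside each training split only,
and the blinded test-fold predictions are pooled into one confusion matrix,
giving one accuracy/sensitivity/specificity triple per repetition. The
clinically worse class (high activity, worsened) is "positive". Summaries
are printed as `mean ± SD%` with half-up rounding to integers. The
permutation null runs the identical procedure with labels permuted once per
repetition; distributions are compared with the two-sided two-sample
Kolmogorov–Smirnov test at p ≤ 0.05.

**A calibration caveat that users should understand.** The observed
ensemble is conditioned on the one true labeling of a single dataset. Even
with no real class effect, a fixed labeling of 40 subjects carries a
dataset-specific spurious cross-validated accuracy offset (SD ≈ 6
percentage points at n = 24/16), while the permutation null marginalizes
over labelings. A two-sample KS test between 100-value distributions
reliably detects offsets of ≳ 2 points, so under the null this comparison
flags "significance" far more often than its nominal level (measured:
12/20 effect-free cohorts). This is a property of the validation scheme
itself, not of the implementation, and it grows worse with more
repetitions. It does not undermine positive findings on strong effects —
cohorts carrying the packaged effect tables separate from their nulls by
30–40 points, far beyond the conditional offset — but a bare KS
"significant" flag on a weak contrast should be interpreted with this
anticonservatism in mind.

## What the simulator does and does not show

The generator reproduces the statistical structure the analysis assumes:
two-class concentration effects, multiplicative biological variation,
realistic spectral overlap, shift jitter and noise, and label-independent
clinical chemistry. It does not simulate pulse-sequence physics (CPMG
relaxation editing, J-modulation, water presaturation), peak-shape
distortions from shimming, inter-batch drift, or correlated metabolite
networks. Passing tests therefore demonstrate that the pipeline recovers
known effects under its stated assumptions — not that those effect sizes
are attainable on any particular clinical cohort.

## Problem sizes

The test and example profiles use 100 cross-validation repetitions,
4096–8192-point spectra and 20-cohort calibration sweeps; the full study
profile (1000 repetitions) is the `CVPolicy` default and scales linearly.
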