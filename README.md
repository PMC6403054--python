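# ucnmr

Plasma ¹H CPMG NMR metabolomics pipeline for ulcerative-colitis disease
activity: cohort simulation, spectral pre-processing into Pareto-scaled
bucket tables, orthogonal PLS discriminant analysis (O-PLS-DA), and ensemble
cross-validation with permutation-null significance testing.

## The problem

Endoscopic assessment is the reference measure of ulcerative-colitis
activity, but sigmoidoscopy is invasive and expensive. A plasma ¹H NMR
metabolite profile is a candidate surrogate: CPMG spectra of plasma resolve
small-molecule metabolites and mobile lipoprotein side chains, and
multivariate models of the bucketed spectra can discriminate low
(UCEIS ≤ 3) from high (UCEIS > 3) endoscopic activity, low (≤ 1) from high
(≥ 3) Nancy histological activity, and — from baseline samples alone —
patients whose endoscopic activity subsequently improves versus worsens.

Because no patient spectra are publicly deposited, the package ships a
first-class synthetic-cohort generator that emulates the study conditions:
~40 subjects at two timepoints, Lorentzian metabolite multiplets plus broad
lipoprotein envelopes on a 0.08–8.50 ppm axis, configurable two-class
effect tables (packaged defaults carry the reported fold changes, e.g.
*myo*-inositol +26% and (-CH₂-)ₙ −36% in high vs low endoscopic activity),
log-normal between-subject variation, chemical-shift jitter, baseline drift
and additive noise, plus a clinical metadata table (UCEIS, Nancy, SCCAI,
bloods, medications, demographics).

## The method

1. **Pre-processing** — FIDs are zero-filled ×2, apodized with 0.30 Hz
   exponential line broadening, Fourier transformed and zero-order phased;
   baselines are removed with an asymmetrically reweighted 3rd-degree
   polynomial; chemical shifts are referenced to the lactate-CH₃ doublet at
   δ = 1.33 ppm; the regions 0.08–4.20 and 5.20–8.50 ppm are integrated into
   371 half-open 0.02-ppm buckets, and the absolute bucket integrals are
   Pareto scaled, `x̃ = (x − x̄)/√s`.
2. **Chemometrics** — PCA for unsupervised overviews, and a from-scratch
   NIPALS O-PLS-DA: one predictive component `t = Xw`, `w ∝ Xᵀy`, plus
   y-orthogonal components sized by internal stratified 7-fold
   cross-validation on Q² = 1 − PRESS/TSS. Discriminating buckets are
   ranked by VIP and selected against a label-permutation null of the
   correlation loading.
3. **Validation** — repeated (default 1000×) balanced external 10-fold
   cross-validation: each repetition undersamples the majority class,
   fits scaler + model on training folds only, pools blinded test-fold
   predictions into one accuracy/sensitivity/specificity triple, and the
   resulting distribution is compared with a label-permutation null via the
   two-sided two-sample Kolmogorov–Smirnov test (significant at p ≤ 0.05).

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_preprocess_to_buckets.py` simulates 40 FIDs carrying the
packaged endoscopic-activity effects, processes them and prints:

```
bucket table: 40 samples × 371 buckets
after Pareto scaling, column variance equals the original SD: max deviation 5.33e-15

metabolite         recovered %diff configured
myo-inositol                 +27.6        +26
(-CH2-)n                     -36.6        -36
isoleucine                   +17.1        +18
glucose                      +10.7        +15
```

i.e. the group percent differences measured at the annotated buckets after
the full pre-processing chain recover the configured concentration effects
to within a few points (the residual is spectral overlap and sampling noise
at n = 24/16). `python examples/05_full_study.py` runs all contrasts and
screens on a simulated longitudinal cohort and prints, per contrast, the
observed and null ensemble summaries ("90 ± 4%" style) and the KS p-value.

A thin CLI mirrors the shell-level steps: `ucnmr simulate`,
`ucnmr preprocess`, `ucnmr report --config <yaml> --outdir <dir>`.

## Layout

- `src/ucnmr/signatures.py` — metabolite signature library + effect tables
  (editable YAML defaults under `src/ucnmr/data/`)
- `src/ucnmr/simulate.py` — cohort and longitudinal-study simulation
- `src/ucnmr/processing.py` — FID processing, bucketing, Pareto scaling
- `src/ucnmr/chemometrics.py` — PCA, O-PLS-DA, VIP, variable selection
- `src/ucnmr/validation.py` — ensemble CV, permutation null, KS comparison
- `src/ucnmr/study.py` — contrast labelling, screens, full study driver
- `docs/methods.md` — model assumptions, parameter choices, limitations
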