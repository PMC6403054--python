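"""Pre-process simulated FIDs into the Pareto-scaled bucket table.

Each FID is zero-filled ×2, apodized with 0.30 Hz line broadening, Fourier
transformed and phased, baseline corrected with a 3rd-degree polynomial,
referenced to the lactate doublet at 1.33 ppm, and integrated into 0.02-ppm
buckets over 0.08–4.20 and 5.20–8.50 ppm (371 buckets; the water region is
discarded).  Pareto scaling divides each mean-centred bucket by the square
root of its standard deviation.
"""

import numpy as np

import ucnmr as u

effects = u.packaged_effect_table("uceis_high_vs_low")
cohort = u.CohortSpec(between_subject_cv=0.05, noise_sd=1.0, master_seed=7)
fids, metadata = u.simulate_cohort(cohort, effects, rng=np.random.default_rng(7),
                                   return_fids=True)
print(f"simulated {len(fids)} FIDs of {fids[0].points.size} complex points")

table = u.process_spectra(fids, list(metadata["sample_id"]))
print(f"bucket table: {table.n_samples} samples × {table.values.shape[1]} buckets")

scaled, scaler = u.pareto_scale(table)
sd = table.values.std(axis=0, ddof=1)
ok = ~scaler.zero_sd
print(f"after Pareto scaling, column variance equals the original SD: "
      f"max deviation {np.abs(scaled.values.var(axis=0, ddof=1)[ok] - sd[ok]).max():.2e}")

# recovered group differences at annotated buckets
library = u.default_metabolite_library()
annotation = u.annotate_buckets(
    {s.name: s.primary_ppm for s in library if s.primary_ppm is not None})
labels = metadata["class_label"].to_numpy()
print(f"\n{'metabolite':18s} {'recovered %diff':>15s} {'configured':>10s}")
for met in ["myo-inositol", "(-CH2-)n", "isoleucine", "glucose"]:
    got = u.percent_difference(table, labels, met, annotation=annotation,
                               case_label="high", control_label="low")
    print(f"{met:18s} {got:+15.1f} {effects.entries[met]:+10.0f}")
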