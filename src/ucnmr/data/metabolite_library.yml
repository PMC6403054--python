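# Default plasma CPMG metabolite signature library.
#
# Chemical shifts, multiplet patterns and linewidths are *literature defaults*
# (HMDB-style reference values for plasma at pH ~7.4), shipped here as an
# editable starting point -- they are not fitted to any particular dataset.
# Broad lipoprotein envelopes are modelled as single wide Lorentzians.
#
# Fields per resonance:
#   center        ppm
#   pattern       relative line intensities (normalized on load)
#   line_spacing  ppm between adjacent multiplet lines (J / observe frequency)
#   linewidth     Hz (full width at half maximum, before apodization)
#   proton_weight effective number of protons contributing to the resonance
#
# primary_ppm marks the resonance used to annotate a bucket to the metabolite.
# baseline_concentration is the default cohort mean, arbitrary units.

metabolites:
  - name: "-CH3"
    kind: lipoprotein
    primary_ppm: 0.875
    baseline_concentration: 60.0
    resonances:
      - {center: 0.875, pattern: [1], line_spacing: 0.0, linewidth: 12.0, proton_weight: 1.0}
  - name: "(-CH2-)n"
    kind: lipoprotein
    primary_ppm: 1.29
    baseline_concentration: 100.0
    resonances:
      - {center: 1.29, pattern: [1], line_spacing: 0.0, linewidth: 12.0, proton_weight: 1.0}
  - name: "beta-CH2"
    kind: lipoprotein
    primary_ppm: 1.57
    baseline_concentration: 30.0
    resonances:
      - {center: 1.57, pattern: [1], line_spacing: 0.0, linewidth: 12.0, proton_weight: 1.0}
  - name: "unsaturated lipid"
    kind: lipoprotein
    primary_ppm: 5.33
    baseline_concentration: 25.0
    resonances:
      - {center: 5.33, pattern: [1], line_spacing: 0.0, linewidth: 10.0, proton_weight: 1.0}
  - name: "=CH-CH2-CH2-"
    kind: lipoprotein
    primary_ppm: 2.02
    baseline_concentration: 20.0
    resonances:
      - {center: 2.02, pattern: [1], line_spacing: 0.0, linewidth: 12.0, proton_weight: 1.0}
  - name: "isoleucine"
    kind: metabolite
    primary_ppm: 1.01
    baseline_concentration: 5.0
    resonances:
      - {center: 0.94, pattern: [1, 2, 1], line_spacing: 0.0106, linewidth: 1.2, proton_weight: 3.0}
      - {center: 1.01, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 3.0}
  - name: "valine"
    kind: metabolite
    primary_ppm: 0.99
    baseline_concentration: 6.0
    resonances:
      - {center: 0.99, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 3.0}
      - {center: 1.04, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 3.0}
  - name: "glucose"
    kind: metabolite
    primary_ppm: 5.23
    baseline_concentration: 15.0
    resonances:
      - {center: 3.25, pattern: [1], line_spacing: 0.0, linewidth: 3.0, proton_weight: 1.0}
      - {center: 3.41, pattern: [1], line_spacing: 0.0, linewidth: 3.0, proton_weight: 1.5}
      - {center: 3.49, pattern: [1], line_spacing: 0.0, linewidth: 3.0, proton_weight: 1.0}
      - {center: 3.72, pattern: [1], line_spacing: 0.0, linewidth: 3.0, proton_weight: 1.5}
      - {center: 3.85, pattern: [1], line_spacing: 0.0, linewidth: 3.0, proton_weight: 1.0}
      - {center: 5.23, pattern: [1], line_spacing: 0.0, linewidth: 1.8, proton_weight: 0.36}
  - name: "myo-inositol"
    kind: metabolite
    primary_ppm: 4.05
    baseline_concentration: 6.0
    resonances:
      - {center: 3.28, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 1.0}
      - {center: 3.54, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 2.0}
      - {center: 3.62, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 2.0}
      - {center: 4.05, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 1.0}
  - name: "lysine"
    kind: metabolite
    primary_ppm: 3.02
    baseline_concentration: 8.0
    resonances:
      - {center: 1.72, pattern: [1, 2, 1], line_spacing: 0.0110, linewidth: 2.5, proton_weight: 2.0}
      - {center: 1.90, pattern: [1, 2, 1], line_spacing: 0.0110, linewidth: 2.5, proton_weight: 2.0}
      - {center: 3.02, pattern: [1], line_spacing: 0.0, linewidth: 2.5, proton_weight: 2.0}
  - name: "histidine"
    kind: metabolite
    primary_ppm: 7.75
    baseline_concentration: 4.0
    resonances:
      - {center: 7.05, pattern: [1], line_spacing: 0.0, linewidth: 1.5, proton_weight: 1.0}
      - {center: 7.75, pattern: [1], line_spacing: 0.0, linewidth: 1.5, proton_weight: 1.0}
  - name: "phenylalanine"
    kind: metabolite
    primary_ppm: 7.37
    baseline_concentration: 4.0
    resonances:
      - {center: 7.32, pattern: [1, 1], line_spacing: 0.0110, linewidth: 1.5, proton_weight: 2.0}
      - {center: 7.37, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 1.0}
      - {center: 7.42, pattern: [1, 2, 1], line_spacing: 0.0110, linewidth: 1.5, proton_weight: 2.0}
  - name: "tyrosine"
    kind: metabolite
    primary_ppm: 6.89
    baseline_concentration: 4.0
    resonances:
      - {center: 6.89, pattern: [1], line_spacing: 0.0, linewidth: 2.2, proton_weight: 2.0}
      - {center: 7.19, pattern: [1, 1], line_spacing: 0.0120, linewidth: 1.5, proton_weight: 2.0}
  - name: "lactate"
    kind: reference
    primary_ppm: 1.33
    baseline_concentration: 20.0
    resonances:
      - {center: 1.33, pattern: [1, 1], line_spacing: 0.0100, linewidth: 1.2, proton_weight: 3.0}
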