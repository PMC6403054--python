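# Packaged effect tables for the three clinical contrasts: signed percent
# change of the case-class mean concentration relative to the control class.
# Metabolite names must resolve against the metabolite signature library.

contrasts:
  uceis_high_vs_low:
    case_class: high
    control_class: low
    entries:
      "-CH3": -25.0
      "(-CH2-)n": -36.0
      "beta-CH2": -37.0
      "unsaturated lipid": -26.0
      "=CH-CH2-CH2-": -15.0
      "isoleucine": 18.0
      "valine": 21.0
      "glucose": 15.0
      "myo-inositol": 26.0
  worsening_vs_improving:
    case_class: worsened
    control_class: improved
    entries:
      "-CH3": 31.0
      "(-CH2-)n": 49.0
      "beta-CH2": 57.0
      "unsaturated lipid": 22.0
      "myo-inositol": 25.0
      "lysine": -10.0
      "histidine": -24.0
      "phenylalanine": -17.0
      "tyrosine": -23.0
  nancy_high_vs_low:
    case_class: high
    control_class: low
    entries:
      "-CH3": -13.0
      "(-CH2-)n": -20.0
      "beta-CH2": -22.0
      "unsaturated lipid": -17.0
      "=CH-CH2-CH2-": -9.0
      "valine": 5.0
      "glucose": 9.0
      "myo-inositol": 26.0
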