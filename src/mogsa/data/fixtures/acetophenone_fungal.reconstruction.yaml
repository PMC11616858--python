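# Synthetic reconstruction of the whole-cell fungal route: Galactomyces
# candidus GZ1 cells grown in a buffered glucose medium at pH 7, reaction
# at room temperature, cells removed by filtration.
schema: mogsa-assessment/1
title: "Biocatalysis 2 (Galactomyces candidus whole cells)"
conditions:
  temperature_C: 25
  ambient_pressure: true
byproducts_formed: false
derivatization_count: 1
monitoring: none
applicability:
  P1: true
  P2: true
  P3: true
  P4: false
  P5: true
  P6: true
  P7: true
  P8: true
  P9: true
  P10: true
  P11: false
  P12: true
substances:
  - name: acetophenone
    roles: [reagent, feedstock]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
    excess_percent: 0
  - name: glucose culture medium
    roles: [feedstock]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: phosphate buffer pH 7
    roles: [solvent]
    hazards: [H290]
    degradability: treatable
    renewable: false
  - name: Galactomyces candidus GZ1 cells
    roles: [catalyst]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: 1-phenylethanol
    roles: [product]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
  - name: spent biomass
    roles: [waste]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
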