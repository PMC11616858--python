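# Synthetic reconstruction of the enzymatic route: a phenylacetaldehyde
# reductase extracted from cultivated cells (lysis + purification steps)
# and used in buffer at 30 degC.
schema: mogsa-assessment/1
title: "Biocatalysis 1 (phenylacetaldehyde reductase)"
conditions:
  temperature_C: 30
  ambient_pressure: true
byproducts_formed: true
derivatization_count: 2
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
  - name: phosphate buffer
    roles: [solvent]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
  - name: 2-propanol
    roles: [auxiliary]
    hazards: [H225, H319, H336]
    degradability: degradable_innocuous
    renewable: false
  - name: cell-lysis detergent
    roles: [auxiliary]
    hazards: [H315]
    degradability: untreatable
    renewable: false
  - name: phenylacetaldehyde reductase preparation
    roles: [catalyst]
    hazards: [H317]
    degradability: treatable
    renewable: true
  - name: NADH cofactor
    roles: [auxiliary]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: (S)-1-phenylethanol
    roles: [product]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
  - name: spent buffer waste
    roles: [waste]
    hazards: [H302]
    degradability: treatable
    renewable: false
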