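# Synthetic reconstruction of the second chemical route: a Ru catalyst on a
# polymeric ligand with sodium formate as reductant, run in water at 40 degC
# under ambient air.
schema: mogsa-assessment/1
title: "Chemical method 2 (Ru-polymer catalyst in water)"
conditions:
  temperature_C: 40
  ambient_pressure: true
byproducts_formed: false
derivatization_count: 0
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
  - name: sodium formate
    roles: [reagent]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
    excess_percent: 15
  - name: water
    roles: [solvent]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: Ru-polymer catalyst
    roles: [catalyst]
    hazards: [H315, H319]
    degradability: treatable
    renewable: false
  - name: 1-phenylethanol
    roles: [product]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
  - name: aqueous formate waste
    roles: [waste]
    hazards: [H302]
    degradability: treatable
    renewable: false
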