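# Synthetic reconstruction of the first chemical route for the catalytic
# stereoselective reduction of acetophenone: a Ru-arene/TsDPEN transfer
# hydrogenation in triethylamine / 2-propanol at 28 degC under air.
# Per-principle inputs are inferred from the published procedure; the
# target product (P4) and process monitoring (P11) are left out of the
# comparison across all four routes.
schema: mogsa-assessment/1
title: "Chemical method 1 (Ru-TsDPEN transfer hydrogenation)"
conditions:
  temperature_C: 28
  ambient_pressure: true
byproducts_formed: false
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
  - name: formic acid
    roles: [reagent]
    hazards: [H226, H314]
    degradability: degradable_innocuous
    renewable: false
    excess_percent: 20
  - name: triethylamine
    roles: [solvent]
    hazards: [H225, H302, H311, H314, H332]
    degradability: treatable
    renewable: false
  - name: 2-propanol
    roles: [solvent]
    hazards: [H225, H319, H336]
    degradability: degradable_innocuous
    renewable: false
  - name: Ru-arene/TsDPEN catalyst
    roles: [catalyst]
    hazards: [H302, H315, H318, H319]
    degradability: untreatable
    renewable: false
  - name: (R)-1-phenylethanol
    roles: [product]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
  - name: recovered solvent residue
    roles: [waste]
    hazards: []
    degradability: treatable
    renewable: false
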