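# Steam distillation with water only; same six selected principles as the
# other two techniques in the teaching comparison.
schema: mogsa-assessment/1
title: "Steam distillation"
conditions:
  temperature_C: 100
  ambient_pressure: true
byproducts_formed: false
derivatization_count: 0
monitoring: none
applicability:
  P1: true
  P2: false
  P3: false
  P4: false
  P5: true
  P6: true
  P7: true
  P8: false
  P9: false
  P10: true
  P11: false
  P12: true
substances:
  - name: plant material
    roles: [feedstock]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: water
    roles: [solvent]
    hazards: []
    degradability: degradable_innocuous
    renewable: true
  - name: aqueous residue
    roles: [waste]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
  - name: essential oil
    roles: [product]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
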