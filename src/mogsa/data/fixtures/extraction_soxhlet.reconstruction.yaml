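# Synthetic reconstruction of a teaching comparison of three sample
# preparation techniques, scored on the six selected principles
# P1, P5, P6, P7, P10 and P12 only; all other principles are excluded
# and render as yellow sectors.  Soxhlet extraction: prolonged reflux of
# n-hexane over plant material.
schema: mogsa-assessment/1
title: "Soxhlet extraction"
conditions:
  temperature_C: 69
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
  - name: n-hexane
    roles: [solvent]
    hazards: [H225, H304, H315, H336, H361, H373, H411]
    degradability: treatable
    renewable: false
  - name: spent hexane
    roles: [waste]
    hazards: [H225, H304, H411]
    degradability: treatable
    renewable: false
  - name: crude extract
    roles: [product]
    hazards: []
    degradability: degradable_innocuous
    renewable: false
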