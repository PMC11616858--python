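# Minimal four-substance assessment (synthetic, for I/O examples): a Ru
# catalyst with triethylamine and 2-propanol as solvents at 28 degC in air.
schema: mogsa-assessment/1
title: "Ru-catalysed reduction, minimal example"
conditions:
  temperature_C: 28
  ambient_pressure: true
byproducts_formed: false
derivatization_count: 0
monitoring: none
applicability:
  P1: true
  P2: true
  P3: true
  P4: true
  P5: true
  P6: true
  P7: true
  P8: true
  P9: true
  P10: true
  P11: true
  P12: true
substances:
  - name: Ru-arene/TsDPEN catalyst
    roles: [catalyst]
    hazards: [H302, H315, H318, H319]
    degradability: untreatable
    renewable: false
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
  - name: (R)-1-phenylethanol
    roles: [product]
    hazards: [H302, H319]
    degradability: treatable
    renewable: false
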