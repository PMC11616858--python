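"""One minimal assessment per published criterion row of the points table.

Each entry is (principle, expected points, label, assessment); the
assessments are built so only the named principle's inputs vary while the
baseline stays neutral.
"""

from __future__ import annotations

from conftest import build_assessment, sub

SCENARIOS = []


def _add(principle: str, points: int, label: str, assessment) -> None:
    SCENARIOS.append((principle, points, label, assessment))


# P1 — prevention: waste hazard to health and the environment
_add("P1", 3, "innocuous waste", build_assessment([sub("w", ["waste"])]))
_add("P1", 2, "moderately hazardous waste", build_assessment([sub("w", ["waste"], ["H302"])]))
_add("P1", 1, "highly hazardous waste", build_assessment([sub("w", ["waste"], ["H400"])]))

# P2 — atom economy: excess reagents (>10%) and byproducts (water excluded)
_add("P2", 3, "<=10% excess, no byproducts",
     build_assessment([sub("r", ["reagent"], excess=5)]))
_add("P2", 2, "<=10% excess, with byproducts",
     build_assessment([sub("r", ["reagent"], excess=5)], byproducts_formed=True))
_add("P2", 2, ">10% excess, no byproducts",
     build_assessment([sub("r", ["reagent"], excess=15)]))
_add("P2", 1, ">10% excess, with byproducts",
     build_assessment([sub("r", ["reagent"], excess=15)], byproducts_formed=True))

# P3 — hazards of all substances (health + environmental)
_add("P3", 3, "all substances innocuous", build_assessment([sub("r", ["reagent"])]))
_add("P3", 2, "moderate hazard present", build_assessment([sub("r", ["reagent"], ["H302"])]))
_add("P3", 1, "high hazard present", build_assessment([sub("r", ["reagent"], ["H301"])]))

# P4 — toxicity of the designed product
_add("P4", 3, "non-toxic product", build_assessment([sub("p", ["product"])]))
_add("P4", 2, "moderately toxic product", build_assessment([sub("p", ["product"], ["H302"])]))
_add("P4", 1, "highly toxic product", build_assessment([sub("p", ["product"], ["H310"])]))

# P5 — solvents and auxiliaries
_add("P5", 3, "no solvents or auxiliaries", build_assessment([]))
_add("P5", 3, "innocuous solvent", build_assessment([sub("water", ["solvent"])]))
_add("P5", 2, "moderate-hazard solvent", build_assessment([sub("s", ["solvent"], ["H226"])]))
_add("P5", 1, "high-hazard auxiliary", build_assessment([sub("s", ["auxiliary"], ["H225"])]))

# P6 — energy: temperature / pressure bands
_add("P6", 3, "room temperature and pressure", build_assessment([], temperature_C=22))
_add("P6", 2, "ambient pressure, heating needed", build_assessment([], temperature_C=40))
_add("P6", 2, "ambient pressure, cooling needed", build_assessment([], temperature_C=5))
_add("P6", 1, "temperature above 100 C", build_assessment([], temperature_C=120))
_add("P6", 1, "temperature below 0 C", build_assessment([], temperature_C=-10))
_add("P6", 1, "non-ambient pressure", build_assessment([], temperature_C=22, ambient_pressure=False))

# P7 — renewable feedstocks
_add("P7", 3, "all feedstocks renewable",
     build_assessment([sub("f1", ["feedstock"], renewable=True),
                       sub("f2", ["feedstock"], renewable=True)]))
_add("P7", 2, "one of two feedstocks renewable",
     build_assessment([sub("f1", ["feedstock"], renewable=True),
                       sub("f2", ["feedstock"], renewable=False)]))
_add("P7", 1, "no renewable feedstocks",
     build_assessment([sub("f1", ["feedstock"], renewable=False)]))

# P8 — derivatizations
_add("P8", 3, "no derivatizations", build_assessment([], derivatization_count=0))
_add("P8", 2, "one derivatization", build_assessment([], derivatization_count=1))
_add("P8", 1, "two derivatizations", build_assessment([], derivatization_count=2))

# P9 — catalysts
_add("P9", 3, "no catalyst", build_assessment([]))
_add("P9", 3, "innocuous catalyst", build_assessment([sub("c", ["catalyst"])]))
_add("P9", 2, "moderate-hazard catalyst", build_assessment([sub("c", ["catalyst"], ["H226"])]))
_add("P9", 1, "high-hazard catalyst", build_assessment([sub("c", ["catalyst"], ["H314"])]))

# P10 — degradability of all substances
_add("P10", 3, "all degradable to innocuous products",
     build_assessment([sub("r", ["reagent"], degradability="degradable_innocuous")]))
_add("P10", 2, "a substance needs treatment",
     build_assessment([sub("r", ["reagent"], degradability="treatable")]))
_add("P10", 1, "an untreatable substance",
     build_assessment([sub("r", ["reagent"], degradability="untreatable")]))

# P11 — monitoring
_add("P11", 3, "continuous monitoring", build_assessment([], monitoring="continuous"))
_add("P11", 2, "periodic monitoring", build_assessment([], monitoring="periodic"))
_add("P11", 1, "no monitoring", build_assessment([], monitoring="none"))

# P12 — accident prevention (physical + health hazards)
_add("P12", 3, "low accident hazard", build_assessment([sub("r", ["reagent"])]))
_add("P12", 2, "moderate accident hazard", build_assessment([sub("r", ["reagent"], ["H302"])]))
_add("P12", 1, "high accident hazard", build_assessment([sub("r", ["reagent"], ["H225"])]))
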