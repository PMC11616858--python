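"""Per-principle point assignment (1-3) for the twelve Green Chemistry principles.

Each applicable principle earns 1, 2 or 3 points.  Most principles reduce
to a worst-case substance severity S in {1,2,3} over the relevant roles
and hazard classes, and then award ``points = 4 - S``; the remaining
principles (P2 atom economy, P6 energy, P7 renewables, P8 derivatives,
P11 monitoring) are scored directly from the declared reaction metadata.

The hazard classes counted per principle follow the principle's scope:

* P1 (waste), P3 (all substances), P4 (products): health + environmental;
* P5 (solvents/auxiliaries), P9 (catalysts): all three classes;
* P12 (accident prevention): physical + health;
* P10: degradability severity; P7: renewability.

Every decision records a rationale naming the matched criterion row, so a
report can be audited against the published rule set.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Callable, Literal, Optional

from pydantic import BaseModel

from .hazards import HazardClass, class_score, degradability_score
from .model import PRINCIPLES, ReactionAssessment, Role, Substance

__all__ = [
    "PrincipleResult",
    "assess_principle",
    "assess_all",
    "principle_criteria",
    "PRINCIPLE_NAMES",
]

PRINCIPLE_NAMES: dict[str, str] = {
    "P1": "Prevention",
    "P2": "Atom Economy",
    "P3": "Less Hazardous Chemical Synthesis",
    "P4": "Designing Safer Chemicals",
    "P5": "Safer Solvents and Auxiliary Substances",
    "P6": "Increase Energy Efficiency",
    "P7": "Use Renewable Feedstocks",
    "P8": "Reduce Derivatives",
    "P9": "Catalysts",
    "P10": "Design for Degradation",
    "P11": "Real-Time Analysis for Pollution Prevention",
    "P12": "Safer Chemistry for Accident Prevention",
}

#: "Room temperature" band in degrees Celsius (inclusive). The criterion
#: "room temperature and pressure" never defines the band numerically;
#: 20-25 degC is the conventional laboratory meaning.
ROOM_TEMPERATURE_RANGE: tuple[float, float] = (20.0, 25.0)

#: Excess-reagent threshold (percent) above which atom economy is penalized.
EXCESS_THRESHOLD_PERCENT: float = 10.0


class PrincipleResult(BaseModel):
    """Outcome of evaluating one principle against one assessment."""

    model_config = {"frozen": True}

    principle: str
    applicable: bool
    points: Optional[Literal[1, 2, 3]] = None
    rationale: str = ""
    warnings: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return PRINCIPLE_NAMES[self.principle]

    def model_post_init(self, __context) -> None:
        if self.applicable and self.points is None:
            raise ValueError(f"{self.principle}: applicable result must carry points")
        if not self.applicable and self.points is not None:
            raise ValueError(f"{self.principle}: non-applicable result must not carry points")


_CRITERIA: Optional[dict[tuple[str, int], list[str]]] = None


def principle_criteria() -> dict[tuple[str, int], list[str]]:
    """Shipped (principle, points) -> criterion texts of the published rule table."""
    global _CRITERIA
    if _CRITERIA is None:
        table: dict[tuple[str, int], list[str]] = {}
        src = resources.files("mogsa").joinpath("data/principle_criteria.csv")
        with src.open("r", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                table.setdefault((row["principle"], int(row["points"])), []).append(
                    row["criterion"]
                )
        _CRITERIA = table
    return _CRITERIA


def _criterion(principle: str, points: int, which: int = 0) -> str:
    return principle_criteria()[(principle, points)][which]


def _hazard_s(
    substances: list[Substance],
    classes: tuple[HazardClass, ...],
    policy: str,
) -> tuple[int, Optional[Substance]]:
    """Worst-case severity over substances x classes, and a driving substance."""
    worst, driver = 1, None
    for s in substances:
        s_val = max(
            class_score(s.hazards, c, unknown_policy=policy).value for c in classes
        )
        if s_val > worst:
            worst, driver = s_val, s
    return worst, driver


def _from_s(
    principle: str,
    s_value: int,
    detail: str,
    warnings: tuple[str, ...] = (),
) -> PrincipleResult:
    points = 4 - s_value
    return PrincipleResult(
        principle=principle,
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion(principle, points)} — {detail}",
        warnings=warnings,
    )


def _not_applicable(principle: str, why: str, warn: bool = False) -> PrincipleResult:
    return PrincipleResult(
        principle=principle,
        applicable=False,
        rationale=why,
        warnings=(why,) if warn else (),
    )


_HEALTH_ENV = (HazardClass.HEALTH, HazardClass.ENVIRONMENTAL)
_ALL_CLASSES = (HazardClass.PHYSICAL, HazardClass.HEALTH, HazardClass.ENVIRONMENTAL)
_PHYS_HEALTH = (HazardClass.PHYSICAL, HazardClass.HEALTH)


def _p1_prevention(a: ReactionAssessment, policy: str) -> PrincipleResult:
    waste = a.with_roles(Role.WASTE)
    warns: tuple[str, ...] = ()
    if not waste:
        # no declared waste: fall back to everything that is not a product
        waste = [s for s in a.substances if not s.has_role(Role.PRODUCT)]
        if waste:
            warns = (
                "no substance carries the waste role; scoring P1 over all "
                "non-product substances",
            )
        else:
            return PrincipleResult(
                principle="P1",
                applicable=True,
                points=3,
                rationale=f"{_criterion('P1', 3)} — no waste is produced",
            )
    s_val, driver = _hazard_s(waste, _HEALTH_ENV, policy)
    detail = (
        f"worst waste severity S={s_val}"
        + (f" (driven by {driver.name})" if driver else " (no health/environmental hazards)")
    )
    return _from_s("P1", s_val, detail, warns)


def _p2_atom_economy(a: ReactionAssessment, policy: str) -> PrincipleResult:
    excesses = [
        s for s in a.with_roles(Role.REAGENT)
        if (s.excess_percent or 0.0) > EXCESS_THRESHOLD_PERCENT
    ]
    over, byp = bool(excesses), bool(a.byproducts_formed)
    points = 3 - int(over) - int(byp)
    which = 1 if (over and not byp) else 0  # the rule table has two 2-point rows
    parts = [
        f"reagents in >{EXCESS_THRESHOLD_PERCENT:g}% excess: "
        + (", ".join(s.name for s in excesses) if excesses else "none"),
        "byproducts formed (water excluded): " + ("yes" if byp else "no"),
    ]
    return PrincipleResult(
        principle="P2",
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion('P2', points, which)} — {'; '.join(parts)}",
    )


def _p3_less_hazardous(a: ReactionAssessment, policy: str) -> PrincipleResult:
    s_val, driver = _hazard_s(a.substances, _HEALTH_ENV, policy)
    detail = f"worst health/environmental severity over all substances S={s_val}" + (
        f" (driven by {driver.name})" if driver else ""
    )
    return _from_s("P3", s_val, detail)


def _p4_safer_chemicals(a: ReactionAssessment, policy: str) -> PrincipleResult:
    products = a.with_roles(Role.PRODUCT)
    if not products:
        return _not_applicable(
            "P4", "no product-role substance declared; P4 cannot be assessed", warn=True
        )
    s_val, driver = _hazard_s(products, _HEALTH_ENV, policy)
    detail = f"worst product toxicity S={s_val}" + (
        f" (driven by {driver.name})" if driver else ""
    )
    return _from_s("P4", s_val, detail)


def _p5_solvents(a: ReactionAssessment, policy: str) -> PrincipleResult:
    aux = [
        s for s in a.substances
        if s.has_role(Role.SOLVENT) or s.has_role(Role.AUXILIARY)
    ]
    if not aux:
        return PrincipleResult(
            principle="P5",
            applicable=True,
            points=3,
            rationale=f"{_criterion('P5', 3)} — no solvents or auxiliary substances used",
        )
    s_val, driver = _hazard_s(aux, _ALL_CLASSES, policy)
    detail = f"worst solvent/auxiliary severity S={s_val}" + (
        f" (driven by {driver.name})" if driver else ""
    )
    return _from_s("P5", s_val, detail)


def _p6_energy(a: ReactionAssessment, policy: str) -> PrincipleResult:
    t = a.conditions.temperature_C
    lo, hi = ROOM_TEMPERATURE_RANGE
    if a.conditions.ambient_pressure and lo <= t <= hi:
        points, detail = 3, f"ambient pressure at room temperature ({t:g} degC)"
    elif a.conditions.ambient_pressure and 0.0 <= t <= 100.0:
        points, detail = 2, f"ambient pressure, {t:g} degC needs heating/cooling"
    else:
        why = "non-ambient pressure" if not a.conditions.ambient_pressure else f"{t:g} degC"
        points, detail = 1, why
    return PrincipleResult(
        principle="P6",
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion('P6', points)} — {detail}",
    )


def _p7_renewables(a: ReactionAssessment, policy: str) -> PrincipleResult:
    feed = a.with_roles(Role.FEEDSTOCK)
    if not feed:
        return _not_applicable(
            "P7", "no feedstock-role substance declared; P7 cannot be assessed", warn=True
        )
    renewable = [s for s in feed if s.degradability.renewable]
    if len(renewable) == len(feed):
        points = 3
    elif renewable:
        points = 2
    else:
        points = 1
    detail = f"{len(renewable)}/{len(feed)} feedstocks renewable"
    return PrincipleResult(
        principle="P7",
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion('P7', points)} — {detail}",
    )


def _p8_derivatives(a: ReactionAssessment, policy: str) -> PrincipleResult:
    n = a.derivatization_count
    points = 3 if n == 0 else (2 if n == 1 else 1)
    return PrincipleResult(
        principle="P8",
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion('P8', points)} — {n} derivatization(s) declared",
    )


def _p9_catalysts(a: ReactionAssessment, policy: str) -> PrincipleResult:
    cats = a.with_roles(Role.CATALYST)
    if not cats:
        return PrincipleResult(
            principle="P9",
            applicable=True,
            points=3,
            rationale=f"{_criterion('P9', 3)} — no catalyst used",
        )
    s_val, driver = _hazard_s(cats, _ALL_CLASSES, policy)
    detail = f"worst catalyst severity S={s_val}" + (
        f" (driven by {driver.name})" if driver else ""
    )
    return _from_s("P9", s_val, detail)


def _p10_degradation(a: ReactionAssessment, policy: str) -> PrincipleResult:
    s_val, driver = max(
        ((degradability_score(s.degradability), s) for s in a.substances),
        key=lambda t: t[0],
    )
    detail = f"worst degradability severity S={s_val} ({driver.name})"
    return _from_s("P10", s_val, detail)


def _p11_monitoring(a: ReactionAssessment, policy: str) -> PrincipleResult:
    points = {"continuous": 3, "periodic": 2, "none": 1}[a.monitoring.value]
    return PrincipleResult(
        principle="P11",
        applicable=True,
        points=points,  # type: ignore[arg-type]
        rationale=f"{_criterion('P11', points)} — monitoring: {a.monitoring.value}",
    )


def _p12_accidents(a: ReactionAssessment, policy: str) -> PrincipleResult:
    s_val, driver = _hazard_s(a.substances, _PHYS_HEALTH, policy)
    detail = f"worst physical/health severity over all substances S={s_val}" + (
        f" (driven by {driver.name})" if driver else ""
    )
    return _from_s("P12", s_val, detail)


_RULES: dict[str, Callable[[ReactionAssessment, str], PrincipleResult]] = {
    "P1": _p1_prevention,
    "P2": _p2_atom_economy,
    "P3": _p3_less_hazardous,
    "P4": _p4_safer_chemicals,
    "P5": _p5_solvents,
    "P6": _p6_energy,
    "P7": _p7_renewables,
    "P8": _p8_derivatives,
    "P9": _p9_catalysts,
    "P10": _p10_degradation,
    "P11": _p11_monitoring,
    "P12": _p12_accidents,
}


def assess_principle(
    p: str,
    a: ReactionAssessment,
    *,
    unknown_policy: Literal["warn", "strict"] = "warn",
) -> PrincipleResult:
    """Evaluate one principle against an assessment.

    Principles masked out by the assessment's applicability map return a
    non-applicable result immediately; principles whose required role is
    absent (P4 without a product, P7 without a feedstock) do the same
    with a warning.
    """
    if p not in PRINCIPLES:
        raise ValueError(f"unknown principle id {p!r}")
    if not a.applicability[p]:
        return _not_applicable(p, "excluded by the assessment's applicability mask")
    return _RULES[p](a, unknown_policy)


def assess_all(
    a: ReactionAssessment,
    *,
    unknown_policy: Literal["warn", "strict"] = "warn",
) -> list[PrincipleResult]:
    """Evaluate all twelve principles, in P1..P12 order."""
    return [assess_principle(p, a, unknown_policy=unknown_policy) for p in PRINCIPLES]
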