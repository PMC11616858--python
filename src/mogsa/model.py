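"""Reaction assessment data model, file I/O and a synthetic generator.

An assessment describes one chemical reaction or process: the substances
involved (each with roles, GHS hazard statements and a degradability /
renewability profile), the reaction conditions, stoichiometry and
workflow metadata, and an applicability mask saying which of the twelve
Green Chemistry principles the user wants scored.

Assessment files are YAML (JSON is a YAML subset and parses too) under
the versioned schema ``mogsa-assessment/1``; substance lists can also be
imported from CSV.
"""

from __future__ import annotations

import csv
import random
import warnings
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .hazards import (
    DegradabilityProfile,
    DegradabilityStatus,
    HazardStatement,
    hazard_table,
    parse_hazard_statement,
)

__all__ = [
    "Role",
    "Monitoring",
    "Substance",
    "ReactionConditions",
    "ReactionAssessment",
    "SchemaError",
    "PRINCIPLES",
    "load_assessment",
    "save_assessment",
    "substances_from_csv",
    "generate_synthetic_assessment",
]

SCHEMA_ID = "mogsa-assessment/1"

#: The twelve Green Chemistry principle ids, in canonical order.
PRINCIPLES: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 13))


class SchemaError(ValueError):
    """An assessment document violates the mogsa-assessment/1 schema."""


class Role(str, Enum):
    REAGENT = "reagent"
    PRODUCT = "product"
    SOLVENT = "solvent"
    AUXILIARY = "auxiliary"
    CATALYST = "catalyst"
    FEEDSTOCK = "feedstock"
    WASTE = "waste"


class Monitoring(str, Enum):
    CONTINUOUS = "continuous"
    PERIODIC = "periodic"
    NONE = "none"


class Substance(BaseModel):
    """A named chemical taking part in the reaction.

    A substance may hold several roles at once (e.g. a solvent that is
    also discarded as waste); each principle then counts it under every
    role it holds.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    name: str = Field(min_length=1)
    roles: frozenset[Role]
    hazards: frozenset[HazardStatement] = frozenset()
    degradability: DegradabilityProfile = DegradabilityProfile(
        status=DegradabilityStatus.TREATABLE, renewable=False
    )
    excess_percent: Optional[float] = None

    @field_validator("roles")
    @classmethod
    def _roles_nonempty(cls, v: frozenset[Role]) -> frozenset[Role]:
        if not v:
            raise ValueError("a substance must hold at least one role")
        return v

    @field_validator("hazards", mode="before")
    @classmethod
    def _parse_hazards(cls, v):
        if isinstance(v, (list, tuple, set, frozenset)):
            return frozenset(
                parse_hazard_statement(h) if isinstance(h, str) else h for h in v
            )
        return v

    @model_validator(mode="after")
    def _excess_needs_reagent_role(self) -> "Substance":
        if self.excess_percent is not None:
            if Role.REAGENT not in self.roles:
                raise ValueError(
                    f"substance {self.name!r}: excess_percent is only meaningful "
                    "for the reagent role"
                )
            if self.excess_percent < 0:
                raise ValueError(f"substance {self.name!r}: excess_percent must be >= 0")
        return self

    def has_role(self, role: Role | str) -> bool:
        return Role(role) in self.roles


class ReactionConditions(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    temperature_C: float
    ambient_pressure: bool = True

    @field_validator("temperature_C")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("temperature must be finite")
        return v


#: Byproducts never counted against atom economy (P2). Water is exempt by
#: definition of the principle's criterion.
DEFAULT_BYPRODUCT_EXEMPTIONS: tuple[str, ...] = ("water",)


class ReactionAssessment(BaseModel):
    """Full description of one reaction for greenness scoring."""

    model_config = {"extra": "forbid"}

    title: str = Field(min_length=1)
    substances: list[Substance] = Field(min_length=1)
    conditions: ReactionConditions
    byproducts_formed: Optional[bool] = None
    byproducts: list[str] = Field(default_factory=list)
    byproduct_exemptions: list[str] = Field(
        default_factory=lambda: list(DEFAULT_BYPRODUCT_EXEMPTIONS)
    )
    derivatization_count: int = Field(default=0, ge=0)
    monitoring: Monitoring = Monitoring.NONE
    applicability: dict[str, bool]

    @field_validator("applicability")
    @classmethod
    def _all_principles(cls, v: dict[str, bool]) -> dict[str, bool]:
        unknown = set(v) - set(PRINCIPLES)
        if unknown:
            raise ValueError(f"unknown principle id(s): {sorted(unknown)}")
        missing = [p for p in PRINCIPLES if p not in v]
        if missing:
            raise ValueError(f"applicability must cover all 12 principles; missing {missing}")
        return {p: v[p] for p in PRINCIPLES}

    @model_validator(mode="after")
    def _resolve_byproducts(self) -> "ReactionAssessment":
        if self.byproducts_formed is None:
            exempt = {e.strip().lower() for e in self.byproduct_exemptions}
            counted = [b for b in self.byproducts if b.strip().lower() not in exempt]
            object.__setattr__(self, "byproducts_formed", bool(counted))
        return self

    def with_roles(self, role: Role | str) -> list[Substance]:
        role = Role(role)
        return [s for s in self.substances if role in s.roles]


# --- serialization ---------------------------------------------------------


def _substance_to_dict(s: Substance) -> dict:
    d: dict = {
        "name": s.name,
        "roles": sorted(r.value for r in s.roles),
        "hazards": sorted(str(h) for h in s.hazards),
        "degradability": s.degradability.status.value,
        "renewable": s.degradability.renewable,
    }
    if s.excess_percent is not None:
        d["excess_percent"] = s.excess_percent
    return d


def assessment_to_dict(a: ReactionAssessment) -> dict:
    return {
        "schema": SCHEMA_ID,
        "title": a.title,
        "conditions": {
            "temperature_C": a.conditions.temperature_C,
            "ambient_pressure": a.conditions.ambient_pressure,
        },
        "byproducts_formed": a.byproducts_formed,
        "derivatization_count": a.derivatization_count,
        "monitoring": a.monitoring.value,
        "applicability": {p: a.applicability[p] for p in PRINCIPLES},
        "substances": [_substance_to_dict(s) for s in a.substances],
    }


def _substance_from_dict(d: dict, *, where: str) -> Substance:
    if not isinstance(d, dict):
        raise SchemaError(f"{where}: expected a mapping, got {type(d).__name__}")
    data = dict(d)
    profile_kwargs = {}
    if "degradability" in data:
        profile_kwargs["status"] = data.pop("degradability")
    if "renewable" in data:
        profile_kwargs["renewable"] = data.pop("renewable")
    try:
        if profile_kwargs:
            data["degradability"] = DegradabilityProfile(**profile_kwargs)
        return Substance(**data)
    except (ValidationError, ValueError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def assessment_from_dict(doc: dict) -> ReactionAssessment:
    """Build a validated assessment from a parsed document."""
    if not isinstance(doc, dict):
        raise SchemaError(f"document root must be a mapping, got {type(doc).__name__}")
    data = dict(doc)
    schema = data.pop("schema", None)
    if schema != SCHEMA_ID:
        raise SchemaError(f"field 'schema': expected {SCHEMA_ID!r}, got {schema!r}")
    raw_substances = data.pop("substances", None)
    if not isinstance(raw_substances, list) or not raw_substances:
        raise SchemaError("field 'substances': a non-empty list is required")
    substances = [
        _substance_from_dict(s, where=f"substances[{i}] ({s.get('name', '?') if isinstance(s, dict) else '?'})")
        for i, s in enumerate(raw_substances)
    ]
    try:
        return ReactionAssessment(substances=substances, **data)
    except (ValidationError, TypeError) as exc:
        raise SchemaError(str(exc)) from exc


def load_assessment(path: str | Path) -> ReactionAssessment:
    """Load and validate a ``mogsa-assessment/1`` YAML or JSON file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML/JSON: {exc}") from exc
    try:
        return assessment_from_dict(doc)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def save_assessment(a: ReactionAssessment, path: str | Path) -> None:
    """Write an assessment back out as canonical YAML (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(assessment_to_dict(a), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


_LIST_SEPARATOR = ";"


def substances_from_csv(path: str | Path) -> list[Substance]:
    """Import substances from CSV.

    Expected columns: ``name, roles, hazard_codes, degradability,
    renewable, excess_percent``; multi-valued cells use ``;``.
    """
    out: list[Substance] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            d = {
                "name": (row.get("name") or "").strip(),
                "roles": [r.strip() for r in (row.get("roles") or "").split(_LIST_SEPARATOR) if r.strip()],
                "hazards": [h.strip() for h in (row.get("hazard_codes") or "").split(_LIST_SEPARATOR) if h.strip()],
            }
            if row.get("degradability"):
                d["degradability"] = row["degradability"].strip()
            if row.get("renewable"):
                d["renewable"] = row["renewable"].strip().lower() in ("1", "true", "yes", "y")
            if row.get("excess_percent"):
                d["excess_percent"] = float(row["excess_percent"])
            out.append(_substance_from_dict(d, where=f"{path} line {i}"))
    return out


# --- synthetic fixture generation -----------------------------------------


def generate_synthetic_assessment(seed: int, n_substances: int = 5) -> ReactionAssessment:
    """Deterministic random assessment for testing and benchmarking.

    Hazard codes (with their qualifiers) are drawn from the shipped score
    table, so every generated statement resolves without the unknown-code
    policy firing.  The first substance is always a product so that P4 can
    be applicable; invariants of the data model always hold.
    """
    if n_substances < 1:
        raise ValueError("n_substances must be >= 1")
    rng = random.Random(seed)
    codes = sorted(hazard_table(), key=lambda k: (k[0], k[1] or ""))
    roles_pool = [r for r in Role if r is not Role.PRODUCT]

    substances: list[Substance] = []
    for i in range(n_substances):
        if i == 0:
            roles = {Role.PRODUCT}
        else:
            roles = set(rng.sample(roles_pool, k=rng.randint(1, 2)))
        hazards = frozenset(
            HazardStatement(code=c, qualifier=q)
            for c, q in rng.sample(codes, k=rng.randint(0, 3))
        )
        excess = None
        if Role.REAGENT in roles and rng.random() < 0.5:
            excess = round(rng.uniform(0, 30), 1)
        substances.append(
            Substance(
                name=f"substance-{i + 1}",
                roles=frozenset(roles),
                hazards=hazards,
                degradability=DegradabilityProfile(
                    status=rng.choice(list(DegradabilityStatus)),
                    renewable=rng.random() < 0.4,
                ),
                excess_percent=excess,
            )
        )

    applicability = {p: rng.random() > 0.15 for p in PRINCIPLES}
    if not any(applicability.values()):
        applicability[rng.choice(PRINCIPLES)] = True

    return ReactionAssessment(
        title=f"synthetic reaction (seed={seed})",
        substances=substances,
        conditions=ReactionConditions(
            temperature_C=round(rng.uniform(-20, 160), 1),
            ambient_pressure=rng.random() < 0.8,
        ),
        byproducts_formed=rng.random() < 0.5,
        derivatization_count=rng.randint(0, 3),
        monitoring=rng.choice(list(Monitoring)),
        applicability=applicability,
    )
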