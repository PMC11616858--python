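"""Shared builders for the test suite.

Everything is constructed programmatically: substances with engineered
hazard severities, twelve-principle point vectors, and the packaged
example fixtures (materialized to tmp dirs when a file path is needed).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pytest

from mogsa import (
    DegradabilityProfile,
    PRINCIPLES,
    PrincipleResult,
    ReactionAssessment,
    ReactionConditions,
    Substance,
)

# representative codes mapping each hazard class to a wanted severity
CODE_FOR = {
    ("physical", 2): "H226",
    ("physical", 3): "H225",
    ("health", 2): "H302",
    ("health", 3): "H301",
    ("environmental", 2): "H402",
    ("environmental", 3): "H400",
}


def sub(
    name: str,
    roles: Sequence[str],
    hazards: Sequence[str] = (),
    degradability: str = "degradable_innocuous",
    renewable: bool = False,
    excess: Optional[float] = None,
) -> Substance:
    return Substance(
        name=name,
        roles=frozenset(roles),
        hazards=list(hazards),
        degradability=DegradabilityProfile(status=degradability, renewable=renewable),
        excess_percent=excess,
    )


def build_assessment(
    substances: Sequence[Substance] = (),
    *,
    temperature_C: float = 22.0,
    ambient_pressure: bool = True,
    byproducts_formed: bool = False,
    derivatization_count: int = 0,
    monitoring: str = "continuous",
    not_applicable: Sequence[str] = (),
    title: str = "test reaction",
) -> ReactionAssessment:
    subs = list(substances)
    if not any(s.has_role("product") for s in subs):
        subs.append(sub("benign product", ["product"]))
    return ReactionAssessment(
        title=title,
        substances=subs,
        conditions=ReactionConditions(
            temperature_C=temperature_C, ambient_pressure=ambient_pressure
        ),
        byproducts_formed=byproducts_formed,
        derivatization_count=derivatization_count,
        monitoring=monitoring,
        applicability={p: p not in set(not_applicable) for p in PRINCIPLES},
    )


def make_results(points: Sequence[Optional[int]]) -> list[PrincipleResult]:
    """Twelve PrincipleResults from a point vector; None marks non-applicable."""
    assert len(points) == 12
    return [
        PrincipleResult(principle=p, applicable=False, rationale="excluded")
        if pts is None
        else PrincipleResult(principle=p, applicable=True, points=pts, rationale="set")
        for p, pts in zip(PRINCIPLES, points)
    ]


FIXTURE_NAMES = [
    "acetophenone_chemical_1.reconstruction.yaml",
    "acetophenone_chemical_2.reconstruction.yaml",
    "acetophenone_enzymatic.reconstruction.yaml",
    "acetophenone_fungal.reconstruction.yaml",
    "extraction_soxhlet.reconstruction.yaml",
    "extraction_microwave.reconstruction.yaml",
    "extraction_steam_distillation.reconstruction.yaml",
    "fujii_like.yaml",
]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """The packaged example fixtures, materialized as real files."""
    out = tmp_path_factory.mktemp("fixtures")
    src = resources.files("mogsa").joinpath("data/fixtures")
    for name in FIXTURE_NAMES:
        (out / name).write_text(src.joinpath(name).read_text(encoding="utf-8"), encoding="utf-8")
    return out
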