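"""Aggregate per-principle points into the overall MoGSA score and band.

The MoGSA score of an assessment with applicable principle points
``p_1..p_n`` (n >= 1, each in {1,2,3}) is

    score = 100 * (p_1 + ... + p_n) / (3 * n)

rounded half-up to two decimals.  Principles marked non-applicable enter
neither the numerator nor the denominator, so excluding an irrelevant
principle re-normalizes the score instead of silently penalizing or
rewarding it.  The score is banded qualitatively:

    score < 50            unacceptable   (red)
    50 <= score < 75      acceptable     (yellow)
    score >= 75           excellent      (green)
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel

from .model import PRINCIPLES
from .principles import PrincipleResult

__all__ = [
    "MoGSAResult",
    "DEFAULT_BAND_THRESHOLDS",
    "BAND_COLORS",
    "FILL_BY_POINTS",
    "compute_score",
    "band",
    "compare",
    "star_area_fraction",
    "save_result",
    "load_result",
]

RESULT_SCHEMA_ID = "mogsa-result/1"

#: (acceptable, excellent) band boundaries on the 0-100 scale.
DEFAULT_BAND_THRESHOLDS: tuple[float, float] = (50.0, 75.0)

BAND_COLORS: dict[str, str] = {
    "unacceptable": "red",
    "acceptable": "yellow",
    "excellent": "green",
}

#: Render-ready sector fill per points value; None encodes non-applicable.
FILL_BY_POINTS: dict[Optional[int], str] = {
    3: "green",
    2: "half-green-half-red",
    1: "red",
    None: "yellow",
}


def band(score: float, thresholds: tuple[float, float] = DEFAULT_BAND_THRESHOLDS) -> str:
    """Qualitative sustainability band for a 0-100 score."""
    lo, hi = thresholds
    if not (0 < lo < hi < 100):
        raise ValueError(f"band thresholds must be strictly increasing in (0, 100): {thresholds}")
    if not (0.0 <= score <= 100.0) or math.isnan(score):
        raise ValueError(f"score must lie in [0, 100], got {score}")
    if score < lo:
        return "unacceptable"
    if score < hi:
        return "acceptable"
    return "excellent"


class MoGSAResult(BaseModel):
    """Twelve principle results plus the aggregate score, band and colors."""

    model_config = {"frozen": True}

    title: str = ""
    results: tuple[PrincipleResult, ...]
    score: float
    band: str
    n_applicable: int
    thresholds: tuple[float, float] = DEFAULT_BAND_THRESHOLDS

    @property
    def sector_fills(self) -> dict[str, str]:
        """Principle id -> fill color name for the star rendering."""
        return {r.principle: FILL_BY_POINTS[r.points] for r in self.results}

    @property
    def bar_color(self) -> str:
        return BAND_COLORS[self.band]

    def points_map(self) -> dict[str, Optional[int]]:
        return {r.principle: r.points for r in self.results}

    def summary(self) -> str:
        lines = [
            f"{self.title or 'assessment'}: MoGSA score {self.score:.2f} ({self.band})",
            f"  applicable principles: {self.n_applicable}/12",
        ]
        for r in self.results:
            pts = "N/A" if r.points is None else f"{r.points}/3"
            lines.append(f"  {r.principle:>3} {r.name:<44} {pts:>4}")
        return "\n".join(lines)


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_score(
    results: Sequence[PrincipleResult],
    *,
    title: str = "",
    thresholds: tuple[float, float] = DEFAULT_BAND_THRESHOLDS,
) -> MoGSAResult:
    """Aggregate exactly twelve principle results into a MoGSAResult.

    Results may arrive in any order; they are stored canonically P1..P12.
    Raises if any principle is missing or duplicated, or if no principle
    is applicable (the score is then undefined).
    """
    by_id = {r.principle: r for r in results}
    if len(results) != 12 or set(by_id) != set(PRINCIPLES):
        raise ValueError(
            f"expected exactly one result per principle P1..P12, got {sorted(by_id)}"
        )
    ordered = tuple(by_id[p] for p in PRINCIPLES)
    applicable = [r for r in ordered if r.applicable]
    if not applicable:
        raise ValueError("no applicable principles: the MoGSA score is undefined")
    total = sum(r.points for r in applicable)  # type: ignore[misc]
    score = _round2_half_up(100.0 * total / (3 * len(applicable)))
    return MoGSAResult(
        title=title,
        results=ordered,
        score=score,
        band=band(score, thresholds),
        n_applicable=len(applicable),
        thresholds=thresholds,
    )


def compare(results: Sequence[MoGSAResult]) -> list[MoGSAResult]:
    """Rank assessments by descending score (stable).

    Ties break first on the number of applicable principles (a score
    backed by more principles ranks first), then keep input order.
    """
    if len(results) < 2:
        raise ValueError("comparison needs at least two assessments")
    return sorted(results, key=lambda r: (-r.score, -r.n_applicable))


def star_area_fraction(result: MoGSAResult) -> float:
    """Geometric star-area ratio over the applicable sectors.

    A secondary, non-canonical statistic: spokes sit at their fixed
    30-degree positions with length points/3, and the cyclic polygon area
    over applicable spokes is normalized by the same polygon at full
    length.  The canonical MoGSA score is the normalized points sum
    computed by :func:`compute_score`, not this area.
    """
    spokes = [
        (math.radians(30.0 * i), r.points / 3.0)
        for i, r in enumerate(result.results)
        if r.applicable
    ]
    if len(spokes) < 2:
        return spokes[0][1] if spokes else 0.0
    area = full = 0.0
    for (t1, r1), (t2, r2) in zip(spokes, spokes[1:] + spokes[:1]):
        wedge = abs(math.sin(t2 - t1))
        area += 0.5 * r1 * r2 * wedge
        full += 0.5 * wedge
    return area / full if full else 0.0


# --- report I/O ------------------------------------------------------------


def _result_to_dict(res: MoGSAResult) -> dict:
    return {
        "schema": RESULT_SCHEMA_ID,
        "title": res.title,
        "score": res.score,
        "band": res.band,
        "bar_color": res.bar_color,
        "n_applicable": res.n_applicable,
        "thresholds": list(res.thresholds),
        "principles": [
            {
                "principle": r.principle,
                "name": r.name,
                "applicable": r.applicable,
                "points": r.points,
                "fill": FILL_BY_POINTS[r.points],
                "rationale": r.rationale,
                "warnings": list(r.warnings),
            }
            for r in res.results
        ],
    }


def save_result(res: MoGSAResult, path: str | Path) -> None:
    """Write a round-trippable JSON report (stable key order, trailing newline)."""
    Path(path).write_text(
        json.dumps(_result_to_dict(res), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def load_result(path: str | Path) -> MoGSAResult:
    """Read a report written by :func:`save_result` back into a MoGSAResult."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != RESULT_SCHEMA_ID:
        raise ValueError(f"{path}: not a {RESULT_SCHEMA_ID} report")
    results = tuple(
        PrincipleResult(
            principle=p["principle"],
            applicable=p["applicable"],
            points=p["points"],
            rationale=p["rationale"],
            warnings=tuple(p["warnings"]),
        )
        for p in doc["principles"]
    )
    return MoGSAResult(
        title=doc["title"],
        results=results,
        score=doc["score"],
        band=doc["band"],
        n_applicable=doc["n_applicable"],
        thresholds=tuple(doc["thresholds"]),
    )
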