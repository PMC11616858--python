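"""GHS hazard statements and their 1-3 greenness severity scores.

The Globally Harmonized System (GHS) labels every classified hazard of a
substance with an H-code: H2xx for physical hazards, H3xx for health
hazards, H4xx for environmental hazards.  For greenness assessment each
code is collapsed onto a three-level severity scale

    1 = Low ("no indication"), 2 = Moderate, 3 = High,

per the code-to-score table shipped with this package
(``data/ghs_hazard_scores.csv``).  A few codes (H228, H242, H261, H272)
change severity with their GHS category or organic-peroxide type, so the
statement optionally carries a qualifier such as ``category 2`` or
``type e``.

Degradability and renewability of a substance are scored on the same
1-3 scale (renewability admits only 1 or 3).
"""

from __future__ import annotations

import csv
import re
import warnings
from enum import Enum
from importlib import resources
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, field_validator

__all__ = [
    "HazardClass",
    "HazardStatement",
    "HazardScore",
    "DegradabilityStatus",
    "DegradabilityProfile",
    "UnknownHazardCodeWarning",
    "MissingQualifierWarning",
    "HazardParseError",
    "UnknownHazardCodeError",
    "parse_hazard_statement",
    "score_statement",
    "class_score",
    "degradability_score",
    "renewability_score",
    "hazard_table",
]


class HazardParseError(ValueError):
    """A hazard token could not be parsed as a GHS H-statement."""


class UnknownHazardCodeError(KeyError):
    """A well-formed H-code is absent from the shipped score table (strict mode)."""


class UnknownHazardCodeWarning(UserWarning):
    """A well-formed H-code is absent from the shipped score table (warn mode)."""


class MissingQualifierWarning(UserWarning):
    """A split-severity code was given without its category/type qualifier."""


class HazardClass(str, Enum):
    PHYSICAL = "physical"
    HEALTH = "health"
    ENVIRONMENTAL = "environmental"


_CLASS_BY_DIGIT = {"2": HazardClass.PHYSICAL, "3": HazardClass.HEALTH, "4": HazardClass.ENVIRONMENTAL}

_LABEL_BY_SCORE = {1: "Low", 2: "Moderate", 3: "High"}


class HazardStatement(BaseModel):
    """One GHS hazard statement: a normalized H-code plus optional qualifier."""

    model_config = {"frozen": True}

    code: str
    qualifier: Optional[str] = None

    @field_validator("code")
    @classmethod
    def _check_code(cls, v: str) -> str:
        if not re.fullmatch(r"H\d{3}", v):
            raise ValueError(f"not a normalized H-code: {v!r}")
        if v[1] not in _CLASS_BY_DIGIT:
            raise ValueError(f"unsupported hazard class for code {v!r}")
        return v

    @field_validator("qualifier")
    @classmethod
    def _normalize_qualifier(cls, v: Optional[str]) -> Optional[str]:
        if v is None:
            return None
        q = re.sub(r"\s+", " ", v.strip().lower())
        q = re.sub(r"^cat\.?\s", "category ", q)
        return q or None

    @property
    def hazard_class(self) -> HazardClass:
        return _CLASS_BY_DIGIT[self.code[1]]

    def __str__(self) -> str:  # e.g. "H272 (category 3)"
        return self.code if self.qualifier is None else f"{self.code} ({self.qualifier})"


class HazardScore(BaseModel):
    """A 1-3 severity score S with its qualitative label."""

    model_config = {"frozen": True}

    value: Literal[1, 2, 3]

    @property
    def classification_label(self) -> str:
        return _LABEL_BY_SCORE[self.value]


class DegradabilityStatus(str, Enum):
    DEGRADABLE_INNOCUOUS = "degradable_innocuous"
    TREATABLE = "treatable"
    UNTREATABLE = "untreatable"


class DegradabilityProfile(BaseModel):
    """End-of-life profile of a substance: degradability status and renewability."""

    model_config = {"frozen": True}

    status: DegradabilityStatus
    renewable: bool = False


_DEGRADABILITY_SCORE = {
    DegradabilityStatus.UNTREATABLE: 3,
    DegradabilityStatus.TREATABLE: 2,
    DegradabilityStatus.DEGRADABLE_INNOCUOUS: 1,
}


def degradability_score(p: DegradabilityProfile) -> int:
    """Severity of a substance's end-of-life fate.

    3 = not degradable and untreatable, 2 = treatable to innocuous
    products, 1 = degradable to innocuous products.
    """
    return _DEGRADABILITY_SCORE[p.status]


def renewability_score(p: DegradabilityProfile) -> int:
    """1 if the substance comes from a renewable source, 3 otherwise."""
    return 1 if p.renewable else 3


# --- score table -----------------------------------------------------------

_TABLE: Optional[dict[tuple[str, Optional[str]], tuple[HazardClass, int]]] = None


def hazard_table() -> dict[tuple[str, Optional[str]], tuple[HazardClass, int]]:
    """The shipped (code, qualifier) -> (class, score) table, loaded once."""
    global _TABLE
    if _TABLE is None:
        table: dict[tuple[str, Optional[str]], tuple[HazardClass, int]] = {}
        src = resources.files("mogsa").joinpath("data/ghs_hazard_scores.csv")
        with src.open("r", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                key = (row["code"], row["qualifier"] or None)
                table[key] = (HazardClass(row["class"]), int(row["score"]))
        _TABLE = table
    return _TABLE


def _split_codes() -> set[str]:
    return {code for code, q in hazard_table() if q is not None}


_TOKEN_RE = re.compile(
    r"""^\s*(?P<code>[A-Za-z]*\d+)\s*(?:\(\s*(?P<qual>[^)]+?)\s*\))?\s*$""",
    re.VERBOSE,
)


def parse_hazard_statement(raw: str) -> HazardStatement:
    """Parse a free-text hazard token such as ``"h272 (Category 3)"``.

    Whitespace- and case-insensitive.  EUH codes and precautionary
    P-statements are rejected explicitly rather than silently ignored,
    since accepting them could hide real hazards from the assessment.
    """
    if not raw or not raw.strip():
        raise HazardParseError("empty hazard token")
    token = raw.strip()
    if re.match(r"^\s*EUH", token, re.IGNORECASE):
        raise HazardParseError(
            f"EUH statement {token!r} is not a GHS H-code and is not scored; remove it"
        )
    if re.match(r"^\s*P\d", token, re.IGNORECASE):
        raise HazardParseError(
            f"precautionary statement {token!r} is not a hazard statement; remove it"
        )
    m = _TOKEN_RE.match(token)
    if not m:
        raise HazardParseError(f"cannot parse hazard token {token!r}")
    code = m.group("code").upper()
    if not code.startswith("H") or not re.fullmatch(r"H\d{3}", code):
        raise HazardParseError(
            f"malformed hazard code {m.group('code')!r} in token {token!r} "
            "(expected 'H' followed by three digits)"
        )
    if code[1] not in _CLASS_BY_DIGIT:
        raise HazardParseError(
            f"hazard code {code!r}: leading digit {code[1]!r} is not a GHS "
            "physical (2), health (3) or environmental (4) class"
        )
    return HazardStatement(code=code, qualifier=m.group("qual"))


def score_statement(
    s: HazardStatement, *, unknown_policy: Literal["warn", "strict"] = "warn"
) -> HazardScore:
    """Map a statement to its 1-3 severity score.

    Split-severity codes missing their qualifier resolve conservatively to
    the more hazardous row (with a warning): greenness must not be
    overstated by missing metadata.  Well-formed codes absent from the
    shipped table score 2 with a warning by default, because the table is
    not the full GHS catalogue and a silent "Low" would understate hazard;
    ``unknown_policy="strict"`` raises instead.
    """
    table = hazard_table()
    key = (s.code, s.qualifier)
    if key in table:
        return HazardScore(value=table[key][1])
    if s.code in _split_codes():
        candidates = [sc for (c, q), (_, sc) in table.items() if c == s.code]
        worst = max(candidates)
        if s.qualifier is None:
            warnings.warn(
                f"{s.code} needs a category/type qualifier to score; assuming the "
                f"more hazardous row (score {worst})",
                MissingQualifierWarning,
                stacklevel=2,
            )
        else:
            warnings.warn(
                f"qualifier {s.qualifier!r} of {s.code} not in the score table; "
                f"assuming the more hazardous row (score {worst})",
                MissingQualifierWarning,
                stacklevel=2,
            )
        return HazardScore(value=worst)
    # qualifier present but the base code is listed unqualified
    if (s.code, None) in table:
        return HazardScore(value=table[(s.code, None)][1])
    if unknown_policy == "strict":
        raise UnknownHazardCodeError(
            f"hazard code {s.code} is not in the shipped score table"
        )
    warnings.warn(
        f"hazard code {s.code} is not in the shipped score table; scoring it 2 "
        "(Moderate) so hazard is not understated",
        UnknownHazardCodeWarning,
        stacklevel=2,
    )
    return HazardScore(value=2)


def class_score(
    statements: Iterable[HazardStatement],
    cls: HazardClass | str,
    *,
    unknown_policy: Literal["warn", "strict"] = "warn",
) -> HazardScore:
    """Worst severity among the statements of one hazard class.

    Returns 1 ("no indication") when no statement of that class is present.
    Monotone under adding statements: more declared hazards can never
    lower the class score.
    """
    cls = HazardClass(cls)
    scores = [
        score_statement(s, unknown_policy=unknown_policy).value
        for s in statements
        if s.hazard_class is cls
    ]
    return HazardScore(value=max(scores) if scores else 1)
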