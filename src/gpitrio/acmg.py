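"""ACMG/AMP evidence combination into a five-tier classification.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5; BA1, BS1-4, BP1-7) carry a
canonical strength but expert judgement may adjust it — for instance
PM3 upgraded from moderate to strong once a variant has been observed
in trans with pathogenic alleles in several unrelated patients. The
combiner works on the EFFECTIVE strengths: an upgraded PM3 counts as a
strong criterion. The combining-rule table is shipped as data
(``data/acmg_rules.json``), not code. Only combination is implemented;
assigning codes to variants is expert work out of scope.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional


class Strength(enum.IntEnum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5

    @classmethod
    def from_name(cls, name: str) -> "Strength":
        return cls[name.upper()]


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


PATHOGENIC_CODES: dict[str, Strength] = {
    "PVS1": Strength.VERY_STRONG,
    **{f"PS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"PM{i}": Strength.MODERATE for i in range(1, 7)},
    **{f"PP{i}": Strength.SUPPORTING for i in range(1, 6)},
}

BENIGN_CODES: dict[str, Strength] = {
    "BA1": Strength.STAND_ALONE,
    **{f"BS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"BP{i}": Strength.SUPPORTING for i in range(1, 8)},
}

CANONICAL_STRENGTH = {**PATHOGENIC_CODES, **BENIGN_CODES}


@dataclass(frozen=True)
class Evidence:
    code: str
    strength: Strength

    @classmethod
    def canonical(cls, code: str) -> "Evidence":
        if code not in CANONICAL_STRENGTH:
            raise ValueError(f"unknown ACMG code: {code}")
        return cls(code, CANONICAL_STRENGTH[code])

    @property
    def is_benign_side(self) -> bool:
        return self.code in BENIGN_CODES


@dataclass(frozen=True)
class Adjustment:
    code: str
    from_strength: Strength
    to_strength: Strength
    reason: str


@dataclass(frozen=True)
class EvidenceSet:
    """One entry per code; adjustments are recorded with their reason."""

    codes: tuple[Evidence, ...] = ()
    adjustments: tuple[Adjustment, ...] = ()

    def __post_init__(self) -> None:
        ids = [e.code for e in self.codes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate evidence code in set")
        for e in self.codes:
            if e.code not in CANONICAL_STRENGTH:
                raise ValueError(f"unknown ACMG code: {e.code}")

    @classmethod
    def of(cls, *codes: str) -> "EvidenceSet":
        return cls(tuple(Evidence.canonical(c) for c in codes))

    @property
    def pathogenic_side(self) -> tuple[Evidence, ...]:
        return tuple(e for e in self.codes if not e.is_benign_side)

    @property
    def benign_side(self) -> tuple[Evidence, ...]:
        return tuple(e for e in self.codes if e.is_benign_side)


def adjust_strength(
    ev: EvidenceSet, code: str, new_strength: Strength, reason: str
) -> EvidenceSet:
    """Return a new set with one code's strength adjusted and audited."""
    match = [e for e in ev.codes if e.code == code]
    if not match:
        raise ValueError(f"code {code} not present in evidence set")
    old = match[0]
    new_codes = tuple(
        Evidence(e.code, new_strength) if e.code == code else e for e in ev.codes
    )
    audit = ev.adjustments + (
        Adjustment(code, old.strength, new_strength, reason),
    )
    return EvidenceSet(new_codes, audit)


def _load_rules() -> dict:
    raw = resources.files("gpitrio.data").joinpath("acmg_rules.json").read_text()
    data = json.loads(raw)
    data.pop("comment", None)
    return data


_RULES = _load_rules()

_TIERS_DESC = (
    Strength.STAND_ALONE,
    Strength.VERY_STRONG,
    Strength.STRONG,
    Strength.MODERATE,
    Strength.SUPPORTING,
)


def _matches(counts: dict[Strength, int], rule: dict[str, int]) -> bool:
    """Greedy allocation: surplus stronger evidence fills weaker slots."""
    available = dict(counts)
    carry = 0
    for tier in _TIERS_DESC:
        carry += available.get(tier, 0)
        need = rule.get(tier.name.lower(), 0)
        if carry < need:
            return False
        carry -= need
    return True


def _side_matches(evidence: Iterable[Evidence], rules: list[dict]) -> bool:
    counts: dict[Strength, int] = {}
    for e in evidence:
        counts[e.strength] = counts.get(e.strength, 0) + 1
    return any(_matches(counts, rule) for rule in rules)


def combine(ev: EvidenceSet) -> Classification:
    """Apply the combining rules on effective strengths.

    Pathogenic outranks likely pathogenic on its own side (likewise
    benign); evidence matching both the pathogenic and benign tables is
    conflicting and yields an uncertain classification, as does
    evidence matching neither.
    """
    pathogenic = _side_matches(ev.pathogenic_side, _RULES["pathogenic"])
    likely_path = pathogenic or _side_matches(
        ev.pathogenic_side, _RULES["likely_pathogenic"]
    )
    benign = _side_matches(ev.benign_side, _RULES["benign"])
    likely_benign = benign or _side_matches(ev.benign_side, _RULES["likely_benign"])

    path_hit = pathogenic or likely_path
    benign_hit = benign or likely_benign
    if path_hit and benign_hit:
        return Classification.UNCERTAIN
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_path:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN
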