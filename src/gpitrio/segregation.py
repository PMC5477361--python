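"""Familial co-segregation probabilities under the null hypothesis.

For a biallelic candidate with two carrier parents, each additional
sibling receives both risk alleles with probability 1/4 under Mendelian
transmission unlinked to disease. The chance that a tested sibling
shows a disease-consistent genotype by luck alone is therefore 1/4 for
an affected carrier sibling and 3/4 for an unaffected non-carrier one;
families multiply over tested siblings and the cohort statistic is the
product over informative families. The statistic is one-sided and
purely combinatorial — descriptive evidence, not a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .inheritance import BIALLELIC_MODELS, Model


@dataclass(frozen=True)
class SiblingOutcome:
    affected: bool
    carries_causal_genotype: bool
    tested: bool = True


@dataclass(frozen=True)
class SegregationObservation:
    family_id: str
    model: Model
    siblings: tuple[SiblingOutcome, ...] = ()

    @property
    def tested_siblings(self) -> tuple[SiblingOutcome, ...]:
        return tuple(s for s in self.siblings if s.tested)

    @property
    def is_consistent(self) -> bool:
        """Every tested affected sibling carries the causal genotype and
        every tested unaffected sibling does not."""
        return all(
            s.carries_causal_genotype == s.affected for s in self.tested_siblings
        )


def sibling_null_probability(
    sib: SiblingOutcome, model: Model
) -> Optional[Fraction]:
    """Null probability of the sibling's observed carrier state.

    Both parents are heterozygous carriers, so a sibling inherits both
    risk alleles with probability 1/4 and fails to with 3/4, whatever
    the affected status. Models without carrier parents (de novo,
    dominant) have no defined sibling probability -> None (NA).
    """
    if model not in BIALLELIC_MODELS:
        return None
    if not sib.tested:
        return None
    return Fraction(1, 4) if sib.carries_causal_genotype else Fraction(3, 4)


def family_null_probability(obs: SegregationObservation) -> Optional[Fraction]:
    """Product over tested siblings; None (NA) when no sibling was tested."""
    tested = obs.tested_siblings
    if not tested:
        return None
    prob = Fraction(1)
    for sib in tested:
        p = sibling_null_probability(sib, obs.model)
        if p is None:
            return None
        prob *= p
    return prob


def combined_null_probability(
    observations: Iterable[SegregationObservation],
) -> Optional[Fraction]:
    """Product of the non-NA family probabilities; None when all are NA."""
    probs = [family_null_probability(o) for o in observations]
    informative = [p for p in probs if p is not None]
    if not informative:
        return None
    prod = Fraction(1)
    for p in informative:
        prod *= p
    return prod


def segregation_report(observations: Sequence[SegregationObservation]) -> dict:
    """JSON-ready block: per-family exact rationals plus the combined value."""
    per_family = {}
    for obs in observations:
        p = family_null_probability(obs)
        per_family[obs.family_id] = {
            "null_probability": None if p is None else str(p),
            "consistent": obs.is_consistent,
            "n_tested_siblings": len(obs.tested_siblings),
        }
    combined = combined_null_probability(observations)
    return {
        "families": per_family,
        "combined_null_probability": None if combined is None else str(combined),
        "combined_rounded": None if combined is None else round(float(combined), 3),
    }
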