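"""Trio genotype classification under Mendelian inheritance models.

A candidate genotype configuration must be consistent with one of three
modes: monoallelic (de novo, or dominantly inherited from an affected
parent), biallelic (homozygous or compound heterozygous in trans) or
X-linked hemizygous. Classification is purely rule-based; genotype
quality is handled upstream by a QC gate, not by an error model.
"""

from __future__ import annotations

import enum
import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    Family,
    Gt,
    Sex,
    TrioRecord,
    VariantSite,
    is_autosome,
    is_pseudoautosomal,
)


class Model(str, enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED_MONOALLELIC = "inherited_monoallelic"
    HOM_BIALLELIC = "hom_biallelic"
    COMPHET_BIALLELIC = "comphet_biallelic"
    X_HEMIZYGOUS = "x_hemizygous"


MONOALLELIC_MODELS = frozenset({Model.DE_NOVO, Model.INHERITED_MONOALLELIC})
BIALLELIC_MODELS = frozenset(
    {Model.HOM_BIALLELIC, Model.COMPHET_BIALLELIC, Model.X_HEMIZYGOUS}
)


class Origin(str, enum.Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    DE_NOVO = "de_novo"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class InheritanceCall:
    """A candidate call: one site, or an ordered (paternal, maternal) pair."""

    model: Model
    variants: tuple[VariantSite, ...]
    origins: tuple[Origin, ...]
    family_id: str = ""

    def __post_init__(self) -> None:
        expected = 2 if self.model == Model.COMPHET_BIALLELIC else 1
        if len(self.variants) != expected or len(self.origins) != expected:
            raise ValueError(
                f"{self.model.value} call requires {expected} site(s)"
            )

    @property
    def gene(self) -> str:
        return self.variants[0].gene

    @property
    def is_biallelic(self) -> bool:
        return self.model in BIALLELIC_MODELS


class MendelianViolation(Exception):
    pass


def classify_site(
    record: TrioRecord, child_sex: Sex = Sex.UNKNOWN
) -> list[tuple[Model, Origin]]:
    """Return every single-site model the trio genotypes are consistent with.

    Autosomal rules (parents non-missing):

    * de_novo — child het or hom_alt, both parents hom_ref
    * inherited_monoallelic — child het, exactly one parent carries the
      allele (origin = that parent); both parents carriers -> ambiguous
    * hom_biallelic — child hom_alt, both parents carriers

    A child hom_alt with a hom_ref parent is Mendelian-inconsistent and
    yields the empty set (possible deletions / uniparental events are
    not modelled). Missing parent genotypes degrade origins to
    ambiguous. Hemizygous child calls are only legal on non-PAR X/Y.
    """
    site = record.site
    child, mother, father = record.child.gt, record.mother.gt, record.father.gt
    if child == Gt.MISSING:
        return []

    on_x = site.chrom.removeprefix("chr") in ("X", "Y")
    if child.is_hemi:
        if is_autosome(site.chrom):
            raise MendelianViolation(
                f"hemizygous genotype on autosome {site.chrom}:{site.pos}"
            )
        if (
            child == Gt.HEMI_ALT
            and not is_pseudoautosomal(site.chrom, site.pos)
            and child_sex == Sex.MALE
            and mother in (Gt.HET,)
            and father in (Gt.HOM_REF, Gt.HEMI_REF)
        ):
            return [(Model.X_HEMIZYGOUS, Origin.MATERNAL)]
        return []
    if on_x and not is_pseudoautosomal(site.chrom, site.pos):
        # diploid-coded X genotypes: treated like the autosomal rules for
        # females; males should arrive hemizygous-coded
        if child_sex == Sex.MALE:
            return []

    if not child.carries_alt:
        return []

    m_carrier = mother.carries_alt
    f_carrier = father.carries_alt
    m_known = mother != Gt.MISSING
    f_known = father != Gt.MISSING

    out: list[tuple[Model, Origin]] = []
    if child == Gt.HET:
        if m_known and f_known:
            if not m_carrier and not f_carrier:
                out.append((Model.DE_NOVO, Origin.DE_NOVO))
            elif mother == Gt.HOM_ALT and father == Gt.HOM_ALT:
                pass  # child het impossible: no parent can transmit ref
            elif m_carrier and f_carrier:
                out.append((Model.INHERITED_MONOALLELIC, Origin.AMBIGUOUS))
            elif f_carrier:
                out.append((Model.INHERITED_MONOALLELIC, Origin.PATERNAL))
            else:
                out.append((Model.INHERITED_MONOALLELIC, Origin.MATERNAL))
        else:
            # one or both parents missing: inheritance cannot be resolved
            out.append((Model.INHERITED_MONOALLELIC, Origin.AMBIGUOUS))
    elif child == Gt.HOM_ALT:
        if m_known and f_known:
            if not m_carrier and not f_carrier:
                out.append((Model.DE_NOVO, Origin.DE_NOVO))
            elif m_carrier and f_carrier:
                out.append((Model.HOM_BIALLELIC, Origin.AMBIGUOUS))
            # exactly one carrier parent: Mendelian-inconsistent, drop
        elif m_carrier or f_carrier:
            out.append((Model.HOM_BIALLELIC, Origin.AMBIGUOUS))
    return out


def site_origin(record: TrioRecord) -> Optional[Origin]:
    """Parental origin of a child-het site, for compound-het pairing.

    paternal/maternal when exactly one parent carries the allele,
    DE_NOVO when neither does, AMBIGUOUS when both do or a parent
    genotype is missing, None when the child is not het.
    """
    if record.child.gt != Gt.HET:
        return None
    m, f = record.mother.gt, record.father.gt
    if m == Gt.MISSING or f == Gt.MISSING:
        return Origin.AMBIGUOUS
    mc, fc = m.carries_alt, f.carries_alt
    if mc and fc:
        return Origin.AMBIGUOUS
    if fc:
        return Origin.PATERNAL
    if mc:
        return Origin.MATERNAL
    return Origin.DE_NOVO


def pair_compound_hets(
    records_in_gene: Sequence[TrioRecord],
    family_id: str = "",
    include_ambiguous: bool = False,
) -> list[InheritanceCall]:
    """Emit trans-configured compound-het pairs within one gene.

    A pair requires one paternal-only and one maternal-only child-het
    site; cis pairs (both from the same parent) are never emitted.
    Sites carried het by both parents have ambiguous phase and are
    excluded unless ``include_ambiguous``, in which case they may pair
    with any opposite-or-ambiguous site and the pair is flagged via
    ambiguous origins.
    """
    genes = {r.site.gene for r in records_in_gene}
    if len(genes) > 1:
        raise ValueError(f"compound-het pairing across genes: {sorted(genes)}")

    paternal, maternal, ambiguous = [], [], []
    for rec in records_in_gene:
        origin = site_origin(rec)
        if origin == Origin.PATERNAL:
            paternal.append(rec)
        elif origin == Origin.MATERNAL:
            maternal.append(rec)
        elif origin == Origin.AMBIGUOUS:
            ambiguous.append(rec)

    def sort_key(r: TrioRecord):
        return (r.site.pos, r.site.ref, r.site.alt)

    calls = []
    for pat, mat in itertools.product(sorted(paternal, key=sort_key),
                                      sorted(maternal, key=sort_key)):
        calls.append(
            InheritanceCall(
                Model.COMPHET_BIALLELIC,
                (pat.site, mat.site),
                (Origin.PATERNAL, Origin.MATERNAL),
                family_id,
            )
        )
    if include_ambiguous:
        for amb in sorted(ambiguous, key=sort_key):
            for other in sorted(paternal + maternal + ambiguous, key=sort_key):
                if other.site == amb.site:
                    continue
                if sort_key(other) < sort_key(amb) and site_origin(other) == Origin.AMBIGUOUS:
                    continue  # emit each ambiguous-ambiguous pair once
                a, b = sorted((amb, other), key=sort_key)
                calls.append(
                    InheritanceCall(
                        Model.COMPHET_BIALLELIC,
                        (a.site, b.site),
                        (Origin.AMBIGUOUS, Origin.AMBIGUOUS),
                        family_id,
                    )
                )
    return calls


def admit_monoallelic(call_origin: Origin, family: Family) -> bool:
    """Dominant-transmission rule for inherited monoallelic candidates.

    Admitted only when the transmitting parent is affected; an
    ambiguous origin requires at least one affected parent (either
    parent could have transmitted).
    """
    if call_origin == Origin.DE_NOVO:
        return True
    if call_origin == Origin.PATERNAL:
        return family.father.affected
    if call_origin == Origin.MATERNAL:
        return family.mother.affected
    return family.father.affected or family.mother.affected


def count_candidates_by_parental_status(
    per_trio: Iterable[tuple[Family, int]]
) -> dict[int, dict]:
    """Mean candidate counts per trio, stratified by affected parents (0/1/2).

    ``per_trio`` yields (family, surviving candidate count). Strata with
    zero trios are absent from the result, not reported as zero.
    """
    strata: dict[int, list[int]] = defaultdict(list)
    for family, count in per_trio:
        strata[family.n_affected_parents].append(count)
    return {
        k: {
            "n_trios": len(v),
            "mean": sum(v) / len(v),
            "min": min(v),
            "max": max(v),
        }
        for k, v in sorted(strata.items())
    }
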