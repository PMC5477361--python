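"""Domain types shared by every pipeline stage.

The pipeline reasons about one variant site at a time, carried together
with the three genotypes of a parent-offspring trio (``TrioRecord``).
Variant-level annotations (gene symbol, consequence class, PolyPhen-2
category, population minor-allele frequency and population homozygote
count) travel on the site itself, read from a deliberately simplified
single-transcript INFO dialect (keys ``GENE``, ``CSQCLASS``, ``PPH2``,
``MAF``, ``NHOM``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence


class Consequence(str, enum.Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER_NONCODING = "other_noncoding"


#: Consequence classes counted as protein altering by the consequence filter.
PROTEIN_ALTERING = frozenset(
    {
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.MISSENSE,
        Consequence.INFRAME_INDEL,
    }
)


class PolyPhen(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"
    UNAVAILABLE = "unavailable"


class Gt(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemi_ref"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Gt.HET, Gt.HOM_ALT, Gt.HEMI_ALT)

    @property
    def is_hemi(self) -> bool:
        return self in (Gt.HEMI_REF, Gt.HEMI_ALT)


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant with its annotations.

    ``maf`` missing from the source is treated as 0.0 (a variant absent
    from the reference cohort is novel); likewise ``hom_count``.
    ``cdna`` is an optional HGVS-like c. identifier used for reporting
    and for counting distinct variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = "."
    consequence: Consequence = Consequence.OTHER_NONCODING
    polyphen: PolyPhen = PolyPhen.UNAVAILABLE
    maf: float = 0.0
    hom_count: int = 0
    qc_pass: bool = True
    cdna: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf must be in [0,1], got {self.maf}")
        if self.hom_count < 0:
            raise ValueError("hom_count must be non-negative")
        if self.alt == self.ref:
            raise ValueError("alt allele equals ref allele")

    @property
    def variant_id(self) -> str:
        """Stable identifier: the c. notation when annotated, else coordinates."""
        if self.cdna:
            return f"{self.gene}:{self.cdna}"
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    gt: Gt
    allele_depths: tuple[int, int] = (0, 0)
    depth: int = 0


@dataclass(frozen=True)
class TrioRecord:
    """A variant site together with the child, mother and father genotypes."""

    site: VariantSite
    child: GenotypeCall
    mother: GenotypeCall
    father: GenotypeCall

    def replace_site(self, **kw) -> "TrioRecord":
        return TrioRecord(
            replace(self.site, **kw), self.child, self.mother, self.father
        )


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Role(str, enum.Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"
    SIBLING = "sibling"


@dataclass(frozen=True)
class Member:
    sample_id: str
    sex: Sex
    role: Role
    affected: bool


@dataclass(frozen=True)
class Family:
    """One sequenced family: exactly one proband trio plus optional siblings."""

    family_id: str
    members: tuple[Member, ...]
    consanguineous: bool = False

    def __post_init__(self) -> None:
        for role in (Role.PROBAND, Role.MOTHER, Role.FATHER):
            n = sum(1 for m in self.members if m.role == role)
            if n != 1:
                raise ValueError(
                    f"family {self.family_id}: expected exactly one {role.value}, got {n}"
                )

    def _one(self, role: Role) -> Member:
        return next(m for m in self.members if m.role == role)

    @property
    def proband(self) -> Member:
        return self._one(Role.PROBAND)

    @property
    def mother(self) -> Member:
        return self._one(Role.MOTHER)

    @property
    def father(self) -> Member:
        return self._one(Role.FATHER)

    @property
    def siblings(self) -> tuple[Member, ...]:
        return tuple(m for m in self.members if m.role == Role.SIBLING)

    @property
    def n_affected_parents(self) -> int:
        return int(self.mother.affected) + int(self.father.affected)


class GenePanel:
    """An ordered set of unique gene symbols."""

    def __init__(self, genes: Iterable[str]):
        seen: dict[str, None] = {}
        for g in genes:
            g = g.strip()
            if not g:
                continue
            if g in seen:
                raise ValueError(f"duplicate gene symbol in panel: {g}")
            seen[g] = None
        if not seen:
            raise ValueError("gene panel is empty")
        self._genes = tuple(seen)

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenePanel) and self._genes == other._genes

    def __repr__(self) -> str:
        return f"GenePanel({list(self._genes)!r})"


#: GPI-anchor-biogenesis pathway genes named in the main analysis; the full
#: clinical panel is config-supplied, this default ships the named members.
DEFAULT_PANEL_GENES = (
    "PGAP3",
    "PIGN",
    "PIGT",
    "PIGO",
    "PIGL",
    "PIGA",
    "PIGV",
    "PIGM",
    "MPPE1",
    "PIGW",
    "PIGS",
    "GPLD1",
    "PIGC",
    "PIGG",
)

#: GRCh37 chromosome lengths (bp) for chr1-22; used as the autosomal
#: denominator of the inbreeding coefficient and by the simulator.
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
}

GRCH37_X_LENGTH = 155_270_560

# GRCh37 X pseudoautosomal regions (1-based inclusive); hemizygous calls
# are only meaningful outside these.
PAR1_X = (60_001, 2_699_520)
PAR2_X = (154_931_044, 155_260_560)


def is_pseudoautosomal(chrom: str, pos: int) -> bool:
    if chrom.removeprefix("chr") not in ("X", "Y"):
        return False
    return PAR1_X[0] <= pos <= PAR1_X[1] or PAR2_X[0] <= pos <= PAR2_X[1]


def is_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    return c.isdigit() and 1 <= int(c) <= 22


@dataclass
class PipelineConfig:
    """Thresholds and switches for the filtering cascade.

    maf_threshold_monoallelic : float
        Upper MAF bound for monoallelic (de novo / dominant) candidates.
    maf_threshold_biallelic : float
        Upper MAF bound applied to each site of a biallelic or X-linked call.
    strict_biallelic_maf : bool
        When True the monoallelic threshold is also applied to biallelic
        calls (the post-review strict mode).
    hom_count_exclusion_min : int
        Minimum population homozygote count that, combined with a MAF
        inside ``hom_count_maf_band``, excludes a biallelic call.
    polyphen_exclude_inherited_benign : bool
        Drop inherited missense variants predicted benign.
    include_ambiguous_comphet : bool
        Emit compound-het pairs in which a site is carried by both
        parents (phase ambiguous) instead of discarding them.
    min_depth / min_allele_fraction
        QC gate applied to the child genotype before classification
        (0 disables; stands in for upstream genotype-quality filtering).
    """

    maf_threshold_monoallelic: float = 0.001
    maf_threshold_biallelic: float = 0.01
    strict_biallelic_maf: bool = False
    hom_count_exclusion_min: int = 2
    hom_count_maf_band: tuple[float, float] = (0.001, 0.01)
    polyphen_exclude_inherited_benign: bool = True
    include_ambiguous_comphet: bool = False
    recessive_focus: bool = True
    min_depth: int = 0
    min_allele_fraction: float = 0.0
    panel: GenePanel = field(default_factory=lambda: GenePanel(DEFAULT_PANEL_GENES))
    autosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(GRCH37_AUTOSOME_LENGTHS)
    )

    def __post_init__(self) -> None:
        for name in ("maf_threshold_monoallelic", "maf_threshold_biallelic"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.hom_count_exclusion_min < 1:
            raise ValueError("hom_count_exclusion_min must be >= 1")


@dataclass
class TrioDataset:
    """One trio's variant records plus bookkeeping used by the simulator.

    ``truth`` carries the planted ground truth (gene, expected fate ...)
    for synthetic cohorts; it is never consulted by the analysis stages.
    """

    family: Family
    records: list[TrioRecord]
    truth: dict = field(default_factory=dict)

    @property
    def trio_id(self) -> str:
        return self.family.proband.sample_id
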