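"""Synthetic trio cohorts with planted causal genotypes.

The generator emits the statistical structure the analysis assumes:
background variant sites with log-uniform population frequencies,
parental genotypes in Hardy-Weinberg proportions and children formed
by Mendelian transmission; six shipped family specifications that
reproduce the published biallelic GPI-pathway genotype configurations
(five compound-heterozygous families and one consanguineous kindred
with a homozygous variant and a second affected brother); decoy
families whose variants must be eliminated at predictable stages; and
a gene-dropping simulator with Poisson recombination that produces
consanguineous genomes together with their true autozygous tracts.

A dummy genome map ships with the module: 22 autosomes plus X at
GRCh37 lengths, with the panel genes placed at fixed, approximately
realistic loci. Real coordinates are unnecessary for the analysis
logic; the map only has to be internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .autozygosity import AllelicRatioPoint, PedigreeGraph
from .model import (
    GRCH37_AUTOSOME_LENGTHS,
    GRCH37_X_LENGTH,
    Consequence,
    Family,
    GenotypeCall,
    Gt,
    Member,
    PolyPhen,
    Role,
    Sex,
    TrioDataset,
    TrioRecord,
    VariantSite,
)
from .segregation import SegregationObservation, SiblingOutcome
from .inheritance import Model
from .splice import TranscriptModel

# ---------------------------------------------------------------------------
# Dummy genome map

#: Panel genes (plus the off-panel SYNGAP1) at fixed synthetic loci,
#: chrom -> (start, end). PIGT sits on chromosome 20 as in the real map.
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "PGAP3": ("17", 37_827_000, 37_845_000),
    "PIGN": ("18", 59_711_000, 59_854_000),
    "PIGT": ("20", 44_045_000, 44_055_000),
    "PIGO": ("9", 35_089_000, 35_097_000),
    "PIGL": ("17", 16_124_000, 16_227_000),
    "PIGA": ("X", 15_319_000, 15_335_000),
    "PIGV": ("1", 27_110_000, 27_122_000),
    "PIGM": ("1", 159_895_000, 159_900_000),
    "MPPE1": ("18", 11_885_000, 11_912_000),
    "PIGW": ("17", 34_893_000, 34_897_000),
    "PIGS": ("17", 26_879_000, 26_899_000),
    "GPLD1": ("6", 24_424_000, 24_495_000),
    "PIGC": ("1", 172_458_000, 172_463_000),
    "PIGG": ("4", 460_000, 500_000),
    "SYNGAP1": ("6", 33_388_000, 33_422_000),
}

_CONSEQ_CLASSES = (
    Consequence.MISSENSE,
    Consequence.SYNONYMOUS,
    Consequence.OTHER_NONCODING,
    Consequence.FRAMESHIFT,
    Consequence.INFRAME_INDEL,
    Consequence.SPLICE_ACCEPTOR,
    Consequence.SPLICE_DONOR,
    Consequence.STOP_GAINED,
)
_CONSEQ_PROBS = np.array([0.40, 0.25, 0.20, 0.04, 0.03, 0.02, 0.02, 0.04])

_PPH_CLASSES = (PolyPhen.BENIGN, PolyPhen.POSSIBLY_DAMAGING, PolyPhen.PROBABLY_DAMAGING)
_PPH_PROBS = np.array([0.55, 0.20, 0.25])

#: Approximate ExAC-scale cohort size used for background homozygote counts.
_REFERENCE_COHORT_N = 60_706

MEAN_DEPTH = 60


def gene_at(chrom: str, pos: int) -> str:
    """Gene symbol for a position: a mapped locus, else a 1 Mb bucket."""
    for gene, (g_chrom, start, end) in GENE_LOCI.items():
        if chrom == g_chrom and start <= pos <= end:
            return gene
    return f"G{chrom}M{pos // 1_000_000}"


def make_trio_family(
    family_id: str,
    proband_id: str,
    proband_sex: Sex = Sex.FEMALE,
    proband_affected: bool = True,
    mother_affected: bool = False,
    father_affected: bool = False,
    consanguineous: bool = False,
    siblings: Sequence[Member] = (),
) -> Family:
    return Family(
        family_id,
        (
            Member(proband_id, proband_sex, Role.PROBAND, proband_affected),
            Member(f"{proband_id}-m", Sex.FEMALE, Role.MOTHER, mother_affected),
            Member(f"{proband_id}-f", Sex.MALE, Role.FATHER, father_affected),
            *siblings,
        ),
        consanguineous=consanguineous,
    )


# ---------------------------------------------------------------------------
# Background trios

_BASES = np.array(["A", "C", "G", "T"])


def generate_background_records(
    n_sites: int,
    rng: np.random.Generator,
    child_id: str,
    mother_id: str,
    father_id: str,
) -> list[TrioRecord]:
    """Background variant sites: HWE parents, Mendelian child."""
    if n_sites == 0:
        return []
    chroms = list(GRCH37_AUTOSOME_LENGTHS)
    lengths = np.array([GRCH37_AUTOSOME_LENGTHS[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=lengths / lengths.sum())
    pos = (rng.random(n_sites) * lengths[chrom_idx]).astype(np.int64) + 1

    # log-uniform MAF on [1e-5, 0.5]
    maf = np.exp(rng.uniform(math.log(1e-5), math.log(0.5), n_sites))

    mother_alt = rng.binomial(2, maf)
    father_alt = rng.binomial(2, maf)

    def transmit(parent_alt: np.ndarray) -> np.ndarray:
        coin = rng.integers(0, 2, n_sites)
        return np.where(parent_alt == 1, coin, parent_alt // 2)

    child_alt = transmit(mother_alt) + transmit(father_alt)

    conseq = rng.choice(len(_CONSEQ_CLASSES), size=n_sites, p=_CONSEQ_PROBS)
    pph = rng.choice(len(_PPH_CLASSES), size=n_sites, p=_PPH_PROBS)
    hom_count = rng.poisson(np.minimum(maf**2 * _REFERENCE_COHORT_N, 1e4))

    depth = np.maximum(rng.poisson(MEAN_DEPTH, size=(n_sites, 3)), 4)
    ref_base = rng.integers(0, 4, n_sites)
    alt_base = (ref_base + rng.integers(1, 4, n_sites)) % 4

    order = np.lexsort((pos, chrom_idx))
    records = []
    gt_codes = (Gt.HOM_REF, Gt.HET, Gt.HOM_ALT)
    for i in order:
        chrom = chroms[chrom_idx[i]]
        site = VariantSite(
            chrom=chrom,
            pos=int(pos[i]),
            ref=str(_BASES[ref_base[i]]),
            alt=str(_BASES[alt_base[i]]),
            gene=gene_at(chrom, int(pos[i])),
            consequence=_CONSEQ_CLASSES[conseq[i]],
            polyphen=(
                _PPH_CLASSES[pph[i]]
                if _CONSEQ_CLASSES[conseq[i]] == Consequence.MISSENSE
                else PolyPhen.UNAVAILABLE
            ),
            maf=float(maf[i]),
            hom_count=int(hom_count[i]),
        )

        def call(sample: str, n_alt: int, dp: int) -> GenotypeCall:
            alt_d = (0, dp // 2, dp)[n_alt]
            return GenotypeCall(sample, gt_codes[n_alt], (dp - alt_d, alt_d), dp)

        records.append(
            TrioRecord(
                site,
                child=call(child_id, int(child_alt[i]), int(depth[i, 0])),
                mother=call(mother_id, int(mother_alt[i]), int(depth[i, 1])),
                father=call(father_id, int(father_alt[i]), int(depth[i, 2])),
            )
        )
    return records


def generate_background_trio(
    n_sites: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    trio_index: int = 0,
    mother_affected: bool = False,
    father_affected: bool = False,
) -> TrioDataset:
    """One synthetic background trio, fully reproducible from the seed."""
    if rng is None:
        rng = np.random.default_rng(seed)
    proband = f"BG{trio_index:04d}"
    family = make_trio_family(
        f"FAM-BG{trio_index:04d}",
        proband,
        proband_sex=Sex.FEMALE if rng.integers(0, 2) else Sex.MALE,
        mother_affected=mother_affected,
        father_affected=father_affected,
    )
    records = generate_background_records(
        n_sites, rng, proband, family.mother.sample_id, family.father.sample_id
    )
    return TrioDataset(family, records, truth={"kind": "background"})


# ---------------------------------------------------------------------------
# Planted families (the published genotype configurations)


@dataclass(frozen=True)
class PlantedVariant:
    cdna: str
    consequence: Consequence
    origin: str  # 'paternal' | 'maternal' | 'both' (homozygous) | 'de_novo'
    maf: float = 0.0
    hom_count: int = 0
    polyphen: PolyPhen = PolyPhen.UNAVAILABLE


@dataclass(frozen=True)
class SiblingSpec:
    sibling_id: str
    affected: bool
    carries_causal_genotype: bool
    tested: bool = True


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    proband_id: str
    gene: str
    variants: tuple[PlantedVariant, ...]
    proband_sex: Sex = Sex.FEMALE
    consanguineous: bool = False
    siblings: tuple[SiblingSpec, ...] = ()
    #: an affected sibling that was exome-sequenced contributes a trio of
    #: its own to the cohort (same parents)
    affected_sibling_trio: Optional[str] = None
    expected_fate: str = "flagged"


def _frac(n: int, d: int) -> float:
    return n / d


#: The six diagnosed families: genotype configurations, parental origins,
#: reference-cohort allele frequencies and sibling outcomes.
SHIPPED_FAMILY_SPECS: tuple[FamilySpec, ...] = (
    FamilySpec(
        "FAM-PGAP3", "257982", "PGAP3",
        (
            PlantedVariant("c.914A>G", Consequence.MISSENSE, "paternal",
                           0.0, 0, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.320C>T", Consequence.MISSENSE, "maternal",
                           _frac(16, 96_004), 0, PolyPhen.PROBABLY_DAMAGING),
        ),
        siblings=(SiblingSpec("257982-s1", True, True),),
    ),
    FamilySpec(
        "FAM-PIGN", "259633", "PIGN",
        (
            PlantedVariant("c.932T>G", Consequence.MISSENSE, "paternal",
                           _frac(2, 38_616), 0, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.694A>T", Consequence.STOP_GAINED, "maternal"),
        ),
        siblings=(
            SiblingSpec("259633-s1", False, False),
            SiblingSpec("259633-s2", False, False),
        ),
    ),
    FamilySpec(
        "FAM-PIGT1", "258094", "PIGT",
        (
            PlantedVariant("c.1582G>A", Consequence.MISSENSE, "maternal",
                           _frac(12, 120_996), 0, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.1730dupC", Consequence.FRAMESHIFT, "paternal",
                           _frac(3, 118_342)),
        ),
        siblings=(SiblingSpec("258094-s1", False, False, tested=False),),
    ),
    FamilySpec(
        "FAM-PIGT2", "270250", "PIGT",
        (
            PlantedVariant("c.709G>C", Consequence.MISSENSE, "both",
                           _frac(8, 100_744), 0, PolyPhen.PROBABLY_DAMAGING),
        ),
        proband_sex=Sex.MALE,
        consanguineous=True,
        siblings=(SiblingSpec("270306", True, True),),
        affected_sibling_trio="270306",
    ),
    FamilySpec(
        "FAM-PIGO", "263039", "PIGO",
        (
            PlantedVariant("c.1306C>T", Consequence.MISSENSE, "maternal",
                           _frac(1, 120_802), 0, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.713G>A", Consequence.MISSENSE, "paternal",
                           0.0, 0, PolyPhen.PROBABLY_DAMAGING),
        ),
        proband_sex=Sex.MALE,
        siblings=(SiblingSpec("263039-s1", False, False),),
    ),
    FamilySpec(
        "FAM-PIGL", "277013", "PIGL",
        (
            PlantedVariant("c.48G>A", Consequence.STOP_GAINED, "maternal",
                           _frac(1, 121_332)),
            PlantedVariant("c.336-2A>G", Consequence.SPLICE_ACCEPTOR, "paternal",
                           _frac(6, 121_410)),
        ),
        siblings=(SiblingSpec("277013-s1", False, False, tested=False),),
    ),
)


#: Decoy families: configurations the cascade must eliminate, each tagged
#: with the stage (or lane) expected to remove it from the flagged lane.
DECOY_SPECS: tuple[FamilySpec, ...] = (
    FamilySpec(
        "FAM-DECOY-PIGM", "D-PIGM", "PIGM",
        (PlantedVariant("c.1199A>G", Consequence.MISSENSE, "de_novo",
                        0.0, 0, PolyPhen.PROBABLY_DAMAGING),),
        expected_fate="monoallelic_panel",
    ),
    FamilySpec(
        "FAM-DECOY-MPPE1", "D-MPPE1", "MPPE1",
        (PlantedVariant("c.682C>T", Consequence.MISSENSE, "de_novo",
                        0.0, 0, PolyPhen.PROBABLY_DAMAGING),),
        expected_fate="monoallelic_panel",
    ),
    FamilySpec(
        "FAM-DECOY-PIGW1", "275308", "PIGW",
        (PlantedVariant("c.705C>G", Consequence.MISSENSE, "both",
                        0.004, 5, PolyPhen.PROBABLY_DAMAGING),),
        expected_fate="hom_count",
    ),
    FamilySpec(
        "FAM-DECOY-PIGW2", "259553", "PIGW",
        (
            PlantedVariant("c.705C>G", Consequence.MISSENSE, "paternal",
                           0.004, 5, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.908G>A", Consequence.MISSENSE, "maternal",
                           0.003, 3, PolyPhen.PROBABLY_DAMAGING),
        ),
        expected_fate="hom_count",
    ),
    FamilySpec(
        "FAM-DECOY-PIGS", "267380", "PIGS",
        (PlantedVariant("c.553C>T", Consequence.MISSENSE, "both",
                        0.002, 4, PolyPhen.PROBABLY_DAMAGING),),
        expected_fate="hom_count",
    ),
    FamilySpec(
        "FAM-DECOY-GPLD1", "276507", "GPLD1",
        (
            PlantedVariant("c.308A>G", Consequence.MISSENSE, "paternal",
                           0.003, 3, PolyPhen.PROBABLY_DAMAGING),
            PlantedVariant("c.2442delA", Consequence.FRAMESHIFT, "maternal",
                           0.0015, 2),
        ),
        expected_fate="hom_count",
    ),
    FamilySpec(
        "FAM-DECOY-SYNGAP1", "258536", "SYNGAP1",
        (PlantedVariant("c.3277C>T", Consequence.STOP_GAINED, "de_novo"),),
        expected_fate="incidental",
    ),
)


def _planted_record(
    variant: PlantedVariant,
    index: int,
    gene: str,
    child_id: str,
    mother_id: str,
    father_id: str,
    child_carries: bool = True,
) -> TrioRecord:
    chrom, start, _end = GENE_LOCI[gene]
    pos = start + 101 * (index + 1)
    if variant.origin == "both":
        child_gt, mother_gt, father_gt = Gt.HOM_ALT, Gt.HET, Gt.HET
    elif variant.origin == "paternal":
        child_gt, mother_gt, father_gt = Gt.HET, Gt.HOM_REF, Gt.HET
    elif variant.origin == "maternal":
        child_gt, mother_gt, father_gt = Gt.HET, Gt.HET, Gt.HOM_REF
    elif variant.origin == "de_novo":
        child_gt, mother_gt, father_gt = Gt.HET, Gt.HOM_REF, Gt.HOM_REF
    else:
        raise ValueError(f"unknown planted origin: {variant.origin}")
    if not child_carries:
        child_gt = Gt.HOM_REF

    def call(sample: str, gt: Gt) -> GenotypeCall:
        ad = {Gt.HOM_REF: (60, 0), Gt.HET: (30, 30), Gt.HOM_ALT: (0, 60)}[gt]
        return GenotypeCall(sample, gt, ad, 60)

    site = VariantSite(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        consequence=variant.consequence,
        polyphen=variant.polyphen,
        maf=variant.maf,
        hom_count=variant.hom_count,
        cdna=variant.cdna,
    )
    return TrioRecord(
        site,
        child=call(child_id, child_gt),
        mother=call(mother_id, mother_gt),
        father=call(father_id, father_gt),
    )


def plant_family(
    spec: FamilySpec,
    rng: Optional[np.random.Generator] = None,
    n_background_sites: int = 0,
) -> list[TrioDataset]:
    """Trio dataset(s) for one family specification.

    Returns the proband trio and, when the spec names an affected
    exome-sequenced sibling, a second trio for that sibling with the
    same parents and the same planted genotypes.
    """
    datasets = []
    probands = [(spec.proband_id, spec.proband_sex)]
    if spec.affected_sibling_trio:
        sib = next(
            s for s in spec.siblings if s.sibling_id == spec.affected_sibling_trio
        )
        if not (sib.affected and sib.carries_causal_genotype):
            raise ValueError("sibling trio requires an affected carrier sibling")
        probands.append((sib.sibling_id, Sex.MALE))

    for proband_id, sex in probands:
        siblings = tuple(
            Member(s.sibling_id, Sex.UNKNOWN, Role.SIBLING, s.affected)
            for s in spec.siblings
            if s.sibling_id != proband_id
        )
        if proband_id != spec.proband_id:
            siblings += (Member(spec.proband_id, spec.proband_sex, Role.SIBLING, True),)
        family = Family(
            spec.family_id,
            (
                Member(proband_id, sex, Role.PROBAND, True),
                Member(f"{spec.proband_id}-m", Sex.FEMALE, Role.MOTHER, False),
                Member(f"{spec.proband_id}-f", Sex.MALE, Role.FATHER, False),
                *siblings,
            ),
            consanguineous=spec.consanguineous,
        )
        records = [
            _planted_record(
                v, i, spec.gene, proband_id,
                family.mother.sample_id, family.father.sample_id,
            )
            for i, v in enumerate(spec.variants)
        ]
        if n_background_sites and rng is not None:
            records += generate_background_records(
                n_background_sites, rng, proband_id,
                family.mother.sample_id, family.father.sample_id,
            )
        records.sort(key=lambda r: (r.site.chrom, r.site.pos))
        datasets.append(
            TrioDataset(
                family,
                records,
                truth={
                    "kind": "planted",
                    "gene": spec.gene,
                    "expected_fate": spec.expected_fate,
                    "spec_family": spec.family_id,
                },
            )
        )
    return datasets


def plant_decoys(
    rng: Optional[np.random.Generator] = None, n_background_sites: int = 0
) -> list[TrioDataset]:
    out = []
    for spec in DECOY_SPECS:
        out.extend(plant_family(spec, rng, n_background_sites))
    return out


def build_cohort(
    n_background_trios: int = 50,
    seed: int = 1,
    n_sites: int = 5000,
    planted: bool = True,
    decoys: bool = True,
    planted_background_sites: Optional[int] = None,
) -> list[TrioDataset]:
    """Background trios + the shipped family specs + the decoys."""
    rng = np.random.default_rng(seed)
    cohort = [
        generate_background_trio(n_sites, rng=rng, trio_index=i)
        for i in range(n_background_trios)
    ]
    pbs = n_sites if planted_background_sites is None else planted_background_sites
    if planted:
        for spec in SHIPPED_FAMILY_SPECS:
            cohort.extend(plant_family(spec, rng, pbs))
    if decoys:
        cohort.extend(plant_decoys(rng, pbs))
    return cohort


def observations_from_specs(
    specs: Sequence[FamilySpec] = SHIPPED_FAMILY_SPECS,
) -> list[SegregationObservation]:
    """Sibling co-segregation observations implied by the family specs."""
    out = []
    for spec in specs:
        model = Model.HOM_BIALLELIC if any(
            v.origin == "both" for v in spec.variants
        ) else Model.COMPHET_BIALLELIC
        out.append(
            SegregationObservation(
                spec.family_id,
                model,
                tuple(
                    SiblingOutcome(s.affected, s.carries_causal_genotype, s.tested)
                    for s in spec.siblings
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene dropping with recombination

Haplotype = tuple[np.ndarray, np.ndarray]  # (segment starts incl. 0, labels)


def _slice_hap(hap: Haplotype, start: float, end: float) -> list[tuple[float, int]]:
    breaks, labels = hap
    i0 = int(np.searchsorted(breaks, start, side="right")) - 1
    i1 = int(np.searchsorted(breaks, end, side="left"))
    out = [(start, int(labels[i0]))]
    for j in range(i0 + 1, i1):
        out.append((float(breaks[j]), int(labels[j])))
    return out


def _meiosis(
    pat: Haplotype, mat: Haplotype, length: float, rng: np.random.Generator
) -> Haplotype:
    """One gamete: Poisson crossovers (mean length_Mb/100), uniform positions."""
    n_x = rng.poisson(length / 1e8)
    cur = int(rng.integers(0, 2))
    haps = (pat, mat)
    if n_x == 0:
        return haps[cur]
    xs = np.sort(rng.uniform(0.0, length, n_x))
    bounds = [0.0, *xs.tolist(), length]
    segs: list[tuple[float, int]] = []
    for i in range(len(bounds) - 1):
        segs.extend(_slice_hap(haps[(cur + i) % 2], bounds[i], bounds[i + 1]))
    # merge adjacent equal labels
    merged = [segs[0]]
    for s, lab in segs[1:]:
        if lab == merged[-1][1]:
            continue
        merged.append((s, lab))
    starts = np.array([s for s, _ in merged])
    labels = np.array([l for _, l in merged], dtype=np.int64)
    return starts, labels


def _autozygous_intervals(
    hap1: Haplotype, hap2: Haplotype, length: float
) -> list[tuple[int, int]]:
    """Maximal intervals where the two haplotype labels coincide."""
    b = np.union1d(hap1[0], hap2[0])
    l1 = hap1[1][np.searchsorted(hap1[0], b, side="right") - 1]
    l2 = hap2[1][np.searchsorted(hap2[0], b, side="right") - 1]
    same = l1 == l2
    out: list[tuple[int, int]] = []
    ends = np.append(b[1:], length)
    for start, end, eq in zip(b, ends, same):
        if not eq:
            continue
        if out and out[-1][1] == int(start):
            out[-1] = (out[-1][0], int(end))
        else:
            out.append((int(start), int(end)))
    return out


@dataclass
class GeneDropResult:
    """Per-individual true autozygous tracts and (optional) marker data."""

    tracts: dict[str, dict[str, list[tuple[int, int]]]]
    points: dict[str, list[AllelicRatioPoint]]
    chrom_lengths: dict[str, int]

    def autozygous_fraction(self, individual: str) -> float:
        genome = sum(self.chrom_lengths.values())
        total = sum(
            e - s
            for intervals in self.tracts[individual].values()
            for s, e in intervals
        )
        return total / genome

    def tract_lengths(self, individual: str) -> list[int]:
        return [
            e - s
            for intervals in self.tracts[individual].values()
            for s, e in intervals
        ]


def simulate_consanguineous_genome(
    pedigree: PedigreeGraph,
    targets: Sequence[str],
    chrom_lengths: Optional[Mapping[str, int]] = None,
    marker_spacing: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    emit_markers: bool = True,
) -> GeneDropResult:
    """Gene-drop founder haplotypes through a pedigree.

    Founders carry two uniquely labelled haplotypes; every meiosis
    recombines with interference-free crossovers. For each target
    individual the result holds the true autozygous tracts (intervals
    where both haplotypes coalesce to one founder haplotype) and,
    optionally, genotype markers: per-marker founder allele frequencies
    are uniform on [0.05, 0.95], founder haplotypes draw alleles from
    them, and the emitted allelic ratio is exact (no read noise).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = dict(chrom_lengths or GRCH37_AUTOSOME_LENGTHS)

    order = sorted(pedigree.individuals(), key=lambda i: pedigree._depth(i, {}))
    founders = [i for i in order if pedigree.parents(i) == (None, None)]
    label_of = {}
    next_label = 0
    for f in founders:
        label_of[f] = (next_label, next_label + 1)
        next_label += 2

    genomes: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    for ind in order:
        father, mother = pedigree.parents(ind)
        genomes[ind] = {}
        for chrom, length in lengths.items():
            if father is None or mother is None:
                a, b = label_of[ind]
                hap1 = (np.array([0.0]), np.array([a], dtype=np.int64))
                hap2 = (np.array([0.0]), np.array([b], dtype=np.int64))
            else:
                hap1 = _meiosis(*genomes[father][chrom], float(length), rng)
                hap2 = _meiosis(*genomes[mother][chrom], float(length), rng)
            genomes[ind][chrom] = (hap1, hap2)

    tracts = {
        t: {
            chrom: _autozygous_intervals(*genomes[t][chrom], float(length))
            for chrom, length in lengths.items()
        }
        for t in targets
    }

    points: dict[str, list[AllelicRatioPoint]] = {t: [] for t in targets}
    if emit_markers:
        n_labels = next_label
        for chrom, length in lengths.items():
            marker_pos = np.arange(marker_spacing, length, marker_spacing)
            freqs = rng.uniform(0.05, 0.95, marker_pos.size)
            alleles = rng.random((n_labels, marker_pos.size)) < freqs
            for t in targets:
                hap1, hap2 = genomes[t][chrom]
                lab1 = hap1[1][np.searchsorted(hap1[0], marker_pos, "right") - 1]
                lab2 = hap2[1][np.searchsorted(hap2[0], marker_pos, "right") - 1]
                a1 = alleles[lab1, np.arange(marker_pos.size)]
                a2 = alleles[lab2, np.arange(marker_pos.size)]
                ratio = (a1.astype(int) + a2.astype(int)) / 2.0
                points[t].extend(
                    AllelicRatioPoint(chrom, int(p), float(r), MEAN_DEPTH)
                    for p, r in zip(marker_pos, ratio)
                )
    return GeneDropResult(tracts, points, lengths)


def first_cousin_pedigree() -> tuple[PedigreeGraph, str]:
    """Shared grandparents; the proband's parents are first cousins."""
    ped = PedigreeGraph()
    for founder in ("GF", "GM", "S1", "S2"):
        ped.add(founder)
    ped.add("P1", "GF", "GM").add("P2", "GF", "GM")
    ped.add("C1", "P1", "S1").add("C2", "P2", "S2")
    ped.add("PROBAND", "C1", "C2")
    return ped, "PROBAND"


def unrelated_pedigree() -> tuple[PedigreeGraph, str]:
    ped = PedigreeGraph()
    ped.add("F").add("M").add("CHILD", "F", "M")
    return ped, "CHILD"


def double_first_cousin_pedigree() -> tuple[PedigreeGraph, str]:
    """The proband's parents are double first cousins (kinship 1/8)."""
    ped = PedigreeGraph()
    for founder in ("A", "B", "C", "D"):
        ped.add(founder)
    ped.add("P1", "A", "B").add("P2", "A", "B")
    ped.add("Q1", "C", "D").add("Q2", "C", "D")
    ped.add("X", "P1", "Q1").add("Y", "P2", "Q2")
    ped.add("PROBAND", "X", "Y")
    return ped, "PROBAND"


# ---------------------------------------------------------------------------
# Transcript fixture for splice-consequence work


def pigl_like_transcript() -> TranscriptModel:
    """A synthetic five-exon transcript emulating the published splice case.

    Exon 3 is 91 bp of coding sequence starting at c.336; skipping it
    shifts the frame so that residue 113 (Asp in the full protein)
    becomes Trp and the next codon is a stop — ``p.D113fs*2``. Exon 5
    skipping is a known naturally occurring isoform.
    """
    cds = (
        "GCT" * 111          # residues 1-111: Ala
        + "GG"               # start of codon 112 (Gly), split by the junction
        + "A"                # c.336: first base of exon 3
        + "GAT"              # residue 113: Asp
        + "GCT" * 29         # remainder of exon 3
        + "TTGGTGAGCTAA"     # exon 4 coding: Leu-Val-Ser-stop
    )
    utr = "ACGT" * 30
    sequence = cds + utr
    return TranscriptModel(
        transcript_id="SYNTH-PIGL-LIKE",
        exon_lengths=(150, 185, 91, 52, 80),
        cds_start=0,
        cds_end=len(cds),
        sequence=sequence,
        known_skipped_isoform_exons=frozenset({5}),
    )
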