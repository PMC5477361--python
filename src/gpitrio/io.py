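"""Readers and writers for the pipeline's on-disk formats.

VCF 4.x input is read through :mod:`cyvcf2`; multi-allelic lines are
decomposed into one biallelic record per ALT allele (alleles other than
the ALT under consideration are recoded as reference). Pedigrees use
the 6-column PED dialect, gene panels are one-symbol-per-line text and
configuration is JSON or YAML.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import yaml
from cyvcf2 import VCF

from .model import (
    Consequence,
    Family,
    GenePanel,
    GenotypeCall,
    Gt,
    Member,
    PipelineConfig,
    Role,
    Sex,
    TrioRecord,
    VariantSite,
)

logger = logging.getLogger(__name__)

INFO_KEYS = ("GENE", "CSQCLASS", "PPH2", "MAF", "NHOM", "CDNA")


# ---------------------------------------------------------------------------
# VCF reading


def _recode(alleles: Sequence[int], alt_index: int) -> Gt:
    """Recode a genotype's allele indices against one ALT allele.

    Alleles equal to ``alt_index`` count as alternate; every other
    non-missing allele (reference or a different ALT) counts as
    reference for this decomposed record.
    """
    if any(a < 0 for a in alleles) or not alleles:
        return Gt.MISSING
    calls = [1 if a == alt_index else 0 for a in alleles]
    if len(calls) == 1:  # haploid call: hemizygous
        return Gt.HEMI_ALT if calls[0] else Gt.HEMI_REF
    n_alt = sum(calls)
    return (Gt.HOM_REF, Gt.HET, Gt.HOM_ALT)[n_alt]


def read_trio_vcf(path: str | Path, family: Family) -> Iterator[TrioRecord]:
    """Stream TrioRecords for one family from a multi-sample VCF.

    Yields one record per ALT allele per locus. Missing sample columns
    are fatal; malformed lines are skipped with a logged warning.
    """
    vcf = VCF(str(path), gts012=False)
    wanted = [
        family.proband.sample_id,
        family.mother.sample_id,
        family.father.sample_id,
    ]
    missing = [s for s in wanted if s not in vcf.samples]
    if missing:
        raise ValueError(f"sample columns absent from {path}: {missing}")
    idx = {s: vcf.samples.index(s) for s in wanted}

    n_skipped = 0
    for variant in vcf:
        try:
            yield from _decompose(variant, wanted, idx)
        except Exception as exc:  # malformed line: skip, keep counting
            n_skipped += 1
            logger.warning("skipping malformed VCF line at %s:%s (%s)",
                           variant.CHROM, variant.POS, exc)
    if n_skipped:
        logger.warning("%d malformed lines skipped in %s", n_skipped, path)


def _decompose(variant, wanted, idx) -> Iterator[TrioRecord]:
    genotypes = variant.genotypes  # [[a1, a2, phased], ...]
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    try:
        dp = variant.format("DP")
    except KeyError:
        dp = None

    gene = variant.INFO.get("GENE") or "."
    csq = variant.INFO.get("CSQCLASS")
    pph = variant.INFO.get("PPH2")
    maf = variant.INFO.get("MAF")
    nhom = variant.INFO.get("NHOM")
    cdna = variant.INFO.get("CDNA")
    qc_pass = variant.FILTER is None  # cyvcf2: None means PASS / '.'

    for alt_i, alt in enumerate(variant.ALT):
        if alt in (".", "*") or alt == variant.REF:
            continue
        site = VariantSite(
            chrom=variant.CHROM,
            pos=variant.POS,
            ref=variant.REF,
            alt=alt,
            gene=gene,
            consequence=Consequence(csq) if csq else Consequence.OTHER_NONCODING,
            polyphen=PolyPhenOrDefault(pph),
            maf=float(maf) if maf is not None else 0.0,
            hom_count=int(nhom) if nhom is not None else 0,
            qc_pass=qc_pass,
            cdna=cdna,
        )
        calls = {}
        for sample in wanted:
            i = idx[sample]
            raw = genotypes[i]
            alleles = [a for a in raw[:-1] if a is not None]
            # cyvcf2 encodes a haploid genotype as a single allele entry
            gt = _recode(alleles, alt_i + 1)
            if ad is not None and len(ad[i]) > alt_i + 1:
                ref_d = max(int(ad[i][0]), 0)
                alt_d = max(int(ad[i][alt_i + 1]), 0)
            else:
                ref_d = alt_d = 0
            depth = int(dp[i][0]) if dp is not None else ref_d + alt_d
            calls[sample] = GenotypeCall(sample, gt, (ref_d, alt_d), depth)
        yield TrioRecord(
            site,
            child=calls[wanted[0]],
            mother=calls[wanted[1]],
            father=calls[wanted[2]],
        )


def PolyPhenOrDefault(value: Optional[str]):
    from .model import PolyPhen

    if value is None:
        return PolyPhen.UNAVAILABLE
    return PolyPhen(value)


# ---------------------------------------------------------------------------
# VCF writing (used by the simulator; plain-text VCF 4.2)

from .model import GRCH37_AUTOSOME_LENGTHS, GRCH37_X_LENGTH

_CONTIG_LINES = "".join(
    f"##contig=<ID={c},length={l}>\n"
    for c, l in {**GRCH37_AUTOSOME_LENGTHS, "X": GRCH37_X_LENGTH}.items()
)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=PPH2,Number=1,Type=String,Description="PolyPhen-2 category">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">
##INFO=<ID=NHOM,Number=1,Type=Integer,Description="Population homozygote count">
##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA-level variant id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
""" + _CONTIG_LINES

_GT_STRING = {
    Gt.HOM_REF: "0/0",
    Gt.HET: "0/1",
    Gt.HOM_ALT: "1/1",
    Gt.HEMI_REF: "0",
    Gt.HEMI_ALT: "1",
    Gt.MISSING: "./.",
}


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_trio_vcf(path: str | Path, records: Iterable[TrioRecord],
                   extra_samples: Optional[dict[str, dict[tuple, GenotypeCall]]] = None) -> None:
    """Write trio records as a multi-sample plain-text VCF.

    ``extra_samples`` maps sample_id -> {(chrom,pos,ref,alt): GenotypeCall}
    and appends additional columns (tested siblings). Sites absent from a
    sibling map are written hom_ref (sibling not carrying).
    """
    records = sorted(records, key=lambda r: (_chrom_key(r.site.chrom), r.site.pos,
                                             r.site.ref, r.site.alt))
    if not records and extra_samples is None:
        samples: list[str] = []
    extra_samples = extra_samples or {}
    sample_names: list[str] = []
    if records:
        r0 = records[0]
        sample_names = [r0.child.sample_id, r0.mother.sample_id, r0.father.sample_id]
    sample_names += list(extra_samples)

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        for s in sample_names:
            fh.write(f"\t{s}")
        fh.write("\n")
        for rec in records:
            s = rec.site
            info = (
                f"GENE={s.gene};CSQCLASS={s.consequence.value};"
                f"PPH2={s.polyphen.value};MAF={s.maf:.9g};NHOM={s.hom_count}"
            )
            if s.cdna:
                info += f";CDNA={s.cdna}"
            filt = "PASS" if s.qc_pass else "lowqual"
            row = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", filt, info, "GT:AD:DP"]
            key = (s.chrom, s.pos, s.ref, s.alt)
            for name, call in (
                ("", rec.child), ("", rec.mother), ("", rec.father)
            ):
                row.append(_format_call(call))
            for sib in extra_samples:
                call = extra_samples[sib].get(
                    key, GenotypeCall(sib, Gt.HOM_REF, (30, 0), 30)
                )
                row.append(_format_call(call))
            fh.write("\t".join(row) + "\n")


def _format_call(call: GenotypeCall) -> str:
    return f"{_GT_STRING[call.gt]}:{call.allele_depths[0]},{call.allele_depths[1]}:{call.depth}"


# ---------------------------------------------------------------------------
# PED reading


def read_ped(path: str | Path) -> list[Family]:
    """Parse a 6-column PED file into Family objects.

    Roles are inferred from parent pointers: an individual whose two
    parents are present in the same family is a child; the first
    affected child (file order) is the proband, remaining children are
    siblings. Phenotype coding: 2 affected, 1 unaffected, 0/-9 unknown.
    """
    rows: dict[str, list[tuple[str, str, str, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line with fewer than 6 columns: {line!r}")
            fam, iid, fid, mid, sex, pheno = parts[:6]
            rows.setdefault(fam, []).append((iid, fid, mid, sex, pheno))

    families = []
    for fam, members in rows.items():
        ids = {m[0] for m in members}
        for iid, fid, mid, _, _ in members:
            for parent in (fid, mid):
                if parent not in ("0", "") and parent not in ids:
                    raise ValueError(
                        f"family {fam}: {iid} references absent parent {parent}"
                    )
        _check_acyclic(fam, members)
        families.append(_build_family(fam, members))
    return families


def _check_acyclic(fam: str, members) -> None:
    parents = {iid: [p for p in (fid, mid) if p not in ("0", "")]
               for iid, fid, mid, _, _ in members}
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise ValueError(f"family {fam}: cyclic parent pointers at {node}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for p in parents.get(node, []):
            visit(p)
        state[node] = 2

    for iid in parents:
        visit(iid)


def _sex(code: str) -> Sex:
    return {"1": Sex.MALE, "2": Sex.FEMALE}.get(code, Sex.UNKNOWN)


def _affected(code: str) -> bool:
    return code == "2"


def _build_family(fam: str, members) -> Family:
    children = [m for m in members if m[1] not in ("0", "") and m[2] not in ("0", "")]
    if not children:
        raise ValueError(f"family {fam}: no individual with two recorded parents")
    affected_children = [c for c in children if _affected(c[4])]
    proband_row = (affected_children or children)[0]
    fid, mid = proband_row[1], proband_row[2]
    by_id = {m[0]: m for m in members}
    out = [
        Member(proband_row[0], _sex(proband_row[3]), Role.PROBAND,
               _affected(proband_row[4])),
        Member(mid, _sex(by_id[mid][3]), Role.MOTHER, _affected(by_id[mid][4])),
        Member(fid, _sex(by_id[fid][3]), Role.FATHER, _affected(by_id[fid][4])),
    ]
    for c in children:
        if c[0] != proband_row[0] and c[1] == fid and c[2] == mid:
            out.append(Member(c[0], _sex(c[3]), Role.SIBLING, _affected(c[4])))
    return Family(fam, tuple(out))


def write_ped(path: str | Path, families: Iterable[Family]) -> None:
    role_parents = {Role.PROBAND: True, Role.SIBLING: True}
    seen: set[tuple[str, str]] = set()
    with open(path, "w") as fh:
        for fam in families:
            father, mother = fam.father.sample_id, fam.mother.sample_id
            for m in fam.members:
                if (fam.family_id, m.sample_id) in seen:
                    continue  # two trios of one family share individuals
                seen.add((fam.family_id, m.sample_id))
                fid = father if m.role in role_parents else "0"
                mid = mother if m.role in role_parents else "0"
                sex = {"male": "1", "female": "2"}.get(m.sex.value, "0")
                pheno = "2" if m.affected else "1"
                fh.write(f"{fam.family_id}\t{m.sample_id}\t{fid}\t{mid}\t{sex}\t{pheno}\n")


# ---------------------------------------------------------------------------
# Panel and config


def read_panel(path: str | Path) -> GenePanel:
    with open(path) as fh:
        return GenePanel(line.strip() for line in fh if line.strip())


def read_config(path: str | Path) -> PipelineConfig:
    """Load a JSON or YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    allowed = {
        "maf_threshold_monoallelic", "maf_threshold_biallelic",
        "strict_biallelic_maf", "hom_count_exclusion_min",
        "hom_count_maf_band", "polyphen_exclude_inherited_benign",
        "include_ambiguous_comphet", "recessive_focus",
        "min_depth", "min_allele_fraction",
        "panel", "autosome_lengths",
    }
    for key, value in raw.items():
        if key not in allowed:
            raise ValueError(f"unknown config key: {key}")
        if key == "panel":
            value = GenePanel(value)
        if key == "hom_count_maf_band":
            value = tuple(value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# Report writers


def write_candidate_report(candidates, path: str | Path) -> None:
    """Write flagged candidates as a deterministic TSV.

    ``candidates`` is an iterable of objects with attributes
    family_id, gene, model, variants (sites), origins. Rows are ordered
    by (family_id, gene, position) so the output is byte-identical for
    any input order.
    """
    rows = []
    for cand in candidates:
        for site, origin in zip(cand.variants, cand.origins):
            rows.append(
                (
                    cand.family_id,
                    site.gene,
                    cand.model.value,
                    site.cdna or f"{site.chrom}:{site.pos}{site.ref}>{site.alt}",
                    origin.value,
                    f"{site.maf:.6g}",
                    str(site.hom_count),
                    site.chrom,
                    site.pos,
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], r[8], r[3]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["family", "gene", "model", "variant", "origin", "maf", "hom_count"]
        )
        for r in rows:
            w.writerow(r[:7])


def write_segments_bed(segments, path: str | Path) -> None:
    """Write autozygosity segments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for seg in sorted(segments, key=lambda s: (_chrom_key(s.chrom), s.start)):
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\n")


def write_segments_tsv(segments, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "n_markers", "het_fraction"])
        for seg in sorted(segments, key=lambda s: (_chrom_key(s.chrom), s.start)):
            w.writerow([seg.chrom, seg.start, seg.end, seg.n_markers,
                        f"{seg.het_fraction:.4f}"])


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
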