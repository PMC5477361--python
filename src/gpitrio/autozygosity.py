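"""Autozygosity mapping and inbreeding coefficients.

Homozygous-by-descent segments are called from per-site allelic ratios
(alt depth over total depth) with a transparent run-length scanner: a
segment is a maximal run of homozygous-looking markers, tolerating a
small budget of heterozygous exceptions per megabase for genotype
error, broken at large inter-marker gaps (exome coverage is uneven).
The observed inbreeding coefficient F is the autosomal fraction covered
by such segments; the pedigree expectation is the kinship coefficient
of the parents (1/16 for first cousins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence
import logging

from cyvcf2 import VCF

from .model import GRCH37_AUTOSOME_LENGTHS, is_autosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AllelicRatioPoint:
    chrom: str
    pos: int
    ratio: float
    depth: int


@dataclass(frozen=True)
class AutozygositySegment:
    chrom: str
    start: int  # bp, 1-based inclusive (first marker of the run)
    end: int    # bp, 1-based inclusive (last marker of the run)
    n_markers: int
    het_fraction: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InbreedingEstimate:
    F: float
    segments: tuple[AutozygositySegment, ...]
    autosomal_length_bp: int


@dataclass
class RohConfig:
    """Parameters of the run-length segment caller.

    hom_ratio_eps : float
        A marker is homozygous-like when ratio <= eps or >= 1 - eps.
    max_het_exceptions_per_mb : float
        Genotype-error budget: heterozygous markers are absorbed into a
        run only when at least 1/rate Mb apart, so a long clean run
        cannot bank exceptions and overrun its true boundary.
    min_segment_mb / min_markers
        Emission gates on segment length and marker support.
    max_gap_mb : float
        Runs are broken when consecutive markers are further apart.
    min_depth : int
        Sites below this depth never enter segmentation.
    """

    hom_ratio_eps: float = 0.1
    max_het_exceptions_per_mb: float = 1.0
    min_segment_mb: float = 2.0
    min_markers: int = 25
    max_gap_mb: float = 3.0
    min_depth: int = 10


def extract_allelic_ratios(
    vcf_path: str, sample_id: str, cfg: Optional[RohConfig] = None
) -> list[AllelicRatioPoint]:
    """High-quality allelic ratios for one sample from a VCF with AD."""
    cfg = cfg or RohConfig()
    vcf = VCF(str(vcf_path))
    if sample_id not in vcf.samples:
        raise ValueError(f"sample {sample_id} absent from {vcf_path}")
    i = vcf.samples.index(sample_id)
    points = []
    for variant in vcf:
        if variant.FILTER is not None:  # non-PASS
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"sample {sample_id}: AD missing at "
                             f"{variant.CHROM}:{variant.POS}")
        ref_d = max(int(ad[i][0]), 0)
        alt_d = max(int(ad[i][1]), 0) if len(ad[i]) > 1 else 0
        depth = ref_d + alt_d
        if depth < cfg.min_depth:
            continue
        points.append(
            AllelicRatioPoint(variant.CHROM, variant.POS, alt_d / depth, depth)
        )
    return points


def call_segments(
    points: Sequence[AllelicRatioPoint], cfg: Optional[RohConfig] = None
) -> list[AutozygositySegment]:
    """Scan sorted ratio points for homozygous-by-descent runs.

    Runs start and end on homozygous-like markers; heterozygous markers
    inside a run are tolerated up to the per-Mb exception budget.
    Input must be sorted by (chrom, pos); unsorted input is fatal.
    """
    cfg = cfg or RohConfig()
    last = None
    for p in points:
        if last is not None and p.chrom == last.chrom and p.pos < last.pos:
            raise ValueError(
                f"unsorted ratio points at {p.chrom}:{p.pos} after {last.pos}"
            )
        last = p

    eps = cfg.hom_ratio_eps
    max_gap = cfg.max_gap_mb * 1e6
    min_het_gap = (
        1e6 / cfg.max_het_exceptions_per_mb
        if cfg.max_het_exceptions_per_mb > 0
        else float("inf")
    )
    segments: list[AutozygositySegment] = []

    run: list[tuple[int, bool]] = []  # (pos, is_het)
    run_chrom: Optional[str] = None
    last_het_pos: Optional[int] = None

    def flush() -> None:
        nonlocal run, last_het_pos
        # trim trailing het markers: runs must end on homozygous evidence
        while run and run[-1][1]:
            run.pop()
        if run:
            start, end = run[0][0], run[-1][0]
            hets = sum(1 for _, h in run if h)
            if (
                end - start >= cfg.min_segment_mb * 1e6
                and len(run) >= cfg.min_markers
            ):
                segments.append(
                    AutozygositySegment(
                        run_chrom, start, end, len(run), hets / len(run)
                    )
                )
        run = []
        last_het_pos = None

    for p in points:
        is_hom = p.ratio <= eps or p.ratio >= 1 - eps
        if run and (p.chrom != run_chrom or p.pos - run[-1][0] > max_gap):
            flush()
        if is_hom:
            if not run:
                run_chrom = p.chrom
            run.append((p.pos, False))
        else:
            if not run:
                continue  # runs never start on a het marker
            if last_het_pos is None or p.pos - last_het_pos >= min_het_gap:
                run.append((p.pos, True))
                last_het_pos = p.pos
            else:
                flush()
    flush()
    return segments


def estimate_inbreeding(
    segments: Iterable[AutozygositySegment],
    autosome_lengths: Optional[Mapping[str, int]] = None,
) -> InbreedingEstimate:
    """F = total autosomal segment length / autosomal genome length.

    X-chromosome segments are excluded. Overlapping segments on one
    chromosome indicate a caller bug and are fatal.
    """
    lengths = autosome_lengths or GRCH37_AUTOSOME_LENGTHS
    autosomal = tuple(
        sorted(
            (s for s in segments if is_autosome(s.chrom)),
            key=lambda s: (s.chrom, s.start),
        )
    )
    by_chrom: dict[str, list[AutozygositySegment]] = {}
    for s in autosomal:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")
    genome = sum(lengths.values())
    total = sum(s.length for s in autosomal)
    return InbreedingEstimate(total / genome, autosomal, genome)


# ---------------------------------------------------------------------------
# Pedigree kinship


class PedigreeGraph:
    """Directed acyclic pedigree; founders are assumed unrelated."""

    def __init__(self) -> None:
        self._parents: dict[str, tuple[Optional[str], Optional[str]]] = {}

    def add(self, individual: str, father: Optional[str] = None,
            mother: Optional[str] = None) -> "PedigreeGraph":
        self._parents[individual] = (father, mother)
        self._check_acyclic(individual)
        return self

    def parents(self, individual: str) -> tuple[Optional[str], Optional[str]]:
        return self._parents.get(individual, (None, None))

    def individuals(self) -> list[str]:
        return list(self._parents)

    def _check_acyclic(self, start: str) -> None:
        seen = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node == start and seen:
                raise ValueError(f"pedigree cycle through {start}")
            if node in seen:
                continue
            seen.add(node)
            stack.extend(p for p in self.parents(node) if p)

    def _depth(self, individual: Optional[str], memo: dict) -> int:
        if individual is None or individual not in self._parents:
            return 0
        if individual in memo:
            return memo[individual]
        f, m = self._parents[individual]
        d = 0 if f is None and m is None else 1 + max(
            self._depth(f, memo), self._depth(m, memo)
        )
        memo[individual] = d
        return d

    def kinship(self, a: Optional[str], b: Optional[str]) -> float:
        """Recursive kinship coefficient; founders: 1/2 with self, 0 pairwise."""
        memo: dict = {}
        depth_memo: dict = {}

        def phi(x: Optional[str], y: Optional[str]) -> float:
            if x is None or y is None:
                return 0.0
            key = (x, y) if x <= y else (y, x)
            if key in memo:
                return memo[key]
            if x == y:
                f, m = self.parents(x)
                val = 0.5 * (1.0 + phi(f, m))
            else:
                if self._depth(x, depth_memo) < self._depth(y, depth_memo):
                    x, y = y, x
                f, m = self.parents(x)
                if f is None and m is None:
                    val = 0.0  # founder, distinct from y
                else:
                    val = 0.5 * (phi(f, y) + phi(m, y))
            memo[key] = val
            return val

        return phi(a, b)


def theoretical_inbreeding(ped: PedigreeGraph, individual: str) -> float:
    """Expected F of ``individual``: the kinship of its parents."""
    father, mother = ped.parents(individual)
    if father is None or mother is None:
        logger.warning("individual %s lacks a recorded parent; F = 0", individual)
        return 0.0
    return ped.kinship(father, mother)


def gene_in_shared_segment(
    segments_per_individual: Mapping[str, Sequence[AutozygositySegment]],
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
) -> tuple[bool, Optional[tuple[int, int]]]:
    """Is the gene contained in an autozygous segment of every individual?

    Containment (not mere overlap) is required for each individual; the
    returned interval is the intersection of the covering segments.
    """
    lo, hi = None, None
    for sample, segments in segments_per_individual.items():
        covering = [
            s
            for s in segments
            if s.chrom == gene_chrom and s.start <= gene_start and s.end >= gene_end
        ]
        if not covering:
            return False, None
        seg = covering[0]
        lo = seg.start if lo is None else max(lo, seg.start)
        hi = seg.end if hi is None else min(hi, seg.end)
    if lo is None:
        return False, None
    return True, (lo, hi)
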