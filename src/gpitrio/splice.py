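"""Exon-skipping consequences at transcript and protein level.

Splice-site variants that abolish an acceptor or donor typically cause
complete skipping of the adjacent exon. Given a transcript's exon
structure and CDS, this module predicts the RT-PCR amplicon size of the
skipped isoform, whether the skip shifts the reading frame (coding exon
length not divisible by three) and the resulting protein notation in
loose HGVS style (``p.D113fs*2``: first altered residue, frameshift,
distance to the new premature stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure plus CDS placement, in transcript coordinates.

    ``cds_start``/``cds_end`` are 0-based offsets into the concatenated
    exon sequence (end exclusive); ``sequence`` is the full spliced
    transcript when protein-level prediction is wanted. Exon numbering
    is 1-based everywhere.
    """

    transcript_id: str
    exon_lengths: tuple[int, ...]
    cds_start: int = 0
    cds_end: Optional[int] = None
    sequence: Optional[str] = None
    strand: str = "+"
    known_skipped_isoform_exons: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        total = sum(self.exon_lengths)
        end = self.cds_end if self.cds_end is not None else total
        if not 0 <= self.cds_start < end <= total:
            raise ValueError("CDS must lie within transcript bounds")
        if self.sequence is not None and len(self.sequence) != total:
            raise ValueError("sequence length does not match exon lengths")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def exon_span(self, exon: int) -> tuple[int, int]:
        """0-based [start, end) of an exon in transcript coordinates."""
        if not 1 <= exon <= self.n_exons:
            raise ValueError(f"exon {exon} outside 1..{self.n_exons}")
        start = sum(self.exon_lengths[: exon - 1])
        return start, start + self.exon_lengths[exon - 1]

    def coding_span_of_exon(self, exon: int) -> tuple[int, int]:
        """Coding portion of an exon as 0-based [start, end) within the CDS."""
        s, e = self.exon_span(exon)
        cds_end = self.cds_end if self.cds_end is not None else sum(self.exon_lengths)
        lo = max(s, self.cds_start)
        hi = min(e, cds_end)
        if hi <= lo:
            return 0, 0
        return lo - self.cds_start, hi - self.cds_start

    def coding_length_of_exon(self, exon: int) -> int:
        lo, hi = self.coding_span_of_exon(exon)
        return hi - lo

    @property
    def cds(self) -> str:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id}: no sequence attached")
        end = self.cds_end if self.cds_end is not None else len(self.sequence)
        return self.sequence[self.cds_start:end]


@dataclass(frozen=True)
class SkipResult:
    skipped_exon: int
    full_amplicon_bp: int
    skipped_amplicon_bp: int
    frameshift: bool
    protein_notation: Optional[str] = None


def amplicon_sizes(
    tx: TranscriptModel,
    fwd_exon: int,
    rev_exon: int,
    full_size_bp: int,
    skipped_exon: int,
) -> tuple[int, int]:
    """Expected RT-PCR product sizes with and without the skipped exon.

    The skipped exon must lie strictly between the primer exons, so the
    skipped product is simply the full product minus the exon length.
    """
    if not fwd_exon < skipped_exon < rev_exon:
        raise ValueError(
            f"skipped exon {skipped_exon} not strictly between primer exons "
            f"{fwd_exon} and {rev_exon}"
        )
    exon_len = tx.exon_lengths[skipped_exon - 1]
    if exon_len >= full_size_bp:
        raise ValueError("skipped exon longer than the full amplicon")
    return full_size_bp, full_size_bp - exon_len


def frameshift_test(exon_coding_length: int) -> bool:
    """True when skipping shifts the reading frame (length % 3 != 0)."""
    if exon_coding_length <= 0:
        raise ValueError("exon coding length must be positive")
    return exon_coding_length % 3 != 0


def _translate(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def protein_consequence(
    tx: TranscriptModel,
    skipped_exon: int,
    coding_sequence: Optional[str] = None,
) -> str:
    """Predict the protein-level notation for an exon skip.

    Translates the intact and the skip-modified CDS, scans for the
    first altered residue and reports either an in-frame deletion
    (``p.(A10_B12del)``) or a frameshift with the distance to the new
    stop (``p.D113fs*2``; ``*?`` plus a warning when no stop is reached
    before the transcript ends).
    """
    cds = coding_sequence if coding_sequence is not None else tx.cds
    lo, hi = tx.coding_span_of_exon(skipped_exon)
    if hi <= lo:
        raise ValueError(f"exon {skipped_exon} is non-coding")
    mutant = cds[:lo] + cds[hi:]
    removed = hi - lo

    full_aa = _translate(cds)
    mut_aa = _translate(mutant)
    full_stop = full_aa.find("*")
    full_protein = full_aa if full_stop < 0 else full_aa[:full_stop]

    # first position where the mutant peptide departs from the wild type
    i = 0
    limit = min(len(full_protein), len(mut_aa))
    while i < limit and mut_aa[i] == full_protein[i]:
        i += 1

    if removed % 3 != 0:
        if i >= len(full_protein):
            ref = "*"
        else:
            ref = full_protein[i]
        if i < len(mut_aa) and mut_aa[i] == "*":
            return f"p.{ref}{i + 1}fs*1"
        stop = mut_aa.find("*", i)
        if stop < 0:
            logger.warning(
                "%s exon %d skip: no stop codon before transcript end",
                tx.transcript_id, skipped_exon,
            )
            return f"p.{ref}{i + 1}fs*?"
        return f"p.{ref}{i + 1}fs*{stop - i + 1}"

    # in-frame skip: a clean deletion of removed//3 residues
    k = removed // 3
    if i >= len(full_protein):
        return "p.(=)"
    first = full_protein[i]
    # a deletion reaching past the stop codon is clamped to the last residue
    last_idx = min(i + k - 1, len(full_protein) - 1)
    if k == 1 or last_idx == i:
        return f"p.({first}{i + 1}del)"
    return f"p.({first}{i + 1}_{full_protein[last_idx]}{last_idx + 1}del)"


def natural_isoform_flag(tx: TranscriptModel, observed_skip: int) -> bool:
    """Does the observed skip match a known alternative isoform?

    A True flag is an interpretation caveat (the band may be the
    naturally occurring isoform), not a pathogenicity call.
    """
    return observed_skip in tx.known_skipped_isoform_exons


def predict_skip(
    tx: TranscriptModel,
    fwd_exon: int,
    rev_exon: int,
    full_size_bp: int,
    skipped_exon: int,
) -> SkipResult:
    """Amplicon sizes, frame status and protein notation for one skip."""
    full, skipped = amplicon_sizes(tx, fwd_exon, rev_exon, full_size_bp, skipped_exon)
    coding_len = tx.coding_length_of_exon(skipped_exon)
    shift = frameshift_test(coding_len) if coding_len else False
    notation = None
    if tx.sequence is not None and coding_len:
        notation = protein_consequence(tx, skipped_exon)
    return SkipResult(skipped_exon, full, skipped, shift, notation)
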