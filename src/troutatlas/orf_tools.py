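"""Six-frame ORF scanning and the interior-ORF full-length cDNA rule.

An ORF is a maximal ATG→stop stretch of clean codons on either strand; a
contig is called a full-length cDNA when its longest ORF both starts after
the first base and ends before the last base of the contig.  Codons
containing ``N`` are neither starts nor stops and invalidate any open ORF
candidate (ORFs never span an ambiguous codon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "OrfCall",
    "FullLengthVerdict",
    "FullLengthCalls",
    "scan_orfs",
    "classify_full_length",
    "call_full_length_set",
    "reverse_complement",
]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """An ORF located on a contig.

    ``start``/``end`` are the 1-based first and last base of the ORF region
    (stop codon included) as an interval on the forward-strand axis; for
    '-' strand calls the translation start codon therefore sits at ``end``.
    ``frame`` is the 0-based frame offset on the ORF's own strand.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    length_nt: int
    protein_length_aa: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length_nt:
            raise ValueError("OrfCall interval inconsistent with length_nt")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def _scan_strand(seq: str, min_aa: int) -> list[tuple[int, int, int]]:
    """Maximal ATG→stop ORFs on one strand: (frame, start0, end0) with
    0-based inclusive coordinates on the given sequence."""
    n = len(seq)
    orfs: list[tuple[int, int, int]] = []
    for frame in range(3):
        open_at: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                open_at = None  # ambiguous codon: ORFs may not span it
            elif codon in STOP_CODONS:
                if open_at is not None:
                    aa = (pos + 3 - open_at) // 3 - 1
                    if aa >= min_aa:
                        orfs.append((frame, open_at, pos + 2))
                    open_at = None
            elif codon == START_CODON and open_at is None:
                open_at = pos
    return orfs


def scan_orfs(
    record: SequenceRecord, min_aa: int = 100, both_strands: bool = True
) -> list[OrfCall]:
    """Find all maximal ATG→stop ORFs with protein length >= ``min_aa``.

    Coordinates are reported on the forward-strand axis regardless of
    strand.  Results are sorted by length descending, ties by (strand,
    start).  A sequence too short to hold any qualifying ORF yields an
    empty list.
    """
    if min_aa < 1:
        raise ValueError(f"min_aa must be >= 1, got {min_aa}")
    seq = record.seq
    n = len(seq)
    calls: list[OrfCall] = []
    for frame, s0, e0 in _scan_strand(seq, min_aa):
        length = e0 - s0 + 1
        calls.append(
            OrfCall(
                contig_id=record.id,
                strand="+",
                frame=frame,
                start=s0 + 1,
                end=e0 + 1,
                length_nt=length,
                protein_length_aa=length // 3 - 1,
            )
        )
    if both_strands:
        rc = reverse_complement(seq)
        for frame, s0, e0 in _scan_strand(rc, min_aa):
            length = e0 - s0 + 1
            # rc interval [s0, e0] maps to forward interval [n-1-e0, n-1-s0]
            calls.append(
                OrfCall(
                    contig_id=record.id,
                    strand="-",
                    frame=frame,
                    start=n - e0,
                    end=n - s0,
                    length_nt=length,
                    protein_length_aa=length // 3 - 1,
                )
            )
    calls.sort(key=lambda o: (-o.length_nt, o.strand, o.start))
    return calls


@dataclass(frozen=True)
class FullLengthVerdict:
    contig_id: str
    is_full_length: bool
    reason: str  # interior | starts_at_first_base | ends_at_last_base | no_orf

    def __post_init__(self) -> None:
        if self.is_full_length != (self.reason == "interior"):
            raise ValueError("is_full_length must be true exactly when reason is 'interior'")


def classify_full_length(seq_length: int, orf: Optional[OrfCall]) -> FullLengthVerdict:
    """Apply the interior-ORF rule: full length iff the ORF neither begins
    at the first base nor ends at the last base of the contig."""
    if orf is None:
        return FullLengthVerdict(contig_id="", is_full_length=False, reason="no_orf")
    if orf.start < 1 or orf.end > seq_length:
        raise ValueError(
            f"ORF [{orf.start}, {orf.end}] outside sequence bounds [1, {seq_length}]"
        )
    if orf.start == 1:
        return FullLengthVerdict(orf.contig_id, False, "starts_at_first_base")
    if orf.end == seq_length:
        return FullLengthVerdict(orf.contig_id, False, "ends_at_last_base")
    return FullLengthVerdict(orf.contig_id, True, "interior")


@dataclass
class FullLengthCalls:
    full_length_ids: set[str]
    verdicts: dict[str, FullLengthVerdict]


def call_full_length_set(
    contigs: Iterable[SequenceRecord], min_aa: int = 100, both_strands: bool = True
) -> FullLengthCalls:
    """Classify the longest ORF of each contig with the interior rule.

    A contig with no qualifying ORF gets reason ``no_orf``.
    """
    verdicts: dict[str, FullLengthVerdict] = {}
    full: set[str] = set()
    for rec in contigs:
        orfs = scan_orfs(rec, min_aa=min_aa, both_strands=both_strands)
        if not orfs:
            verdicts[rec.id] = FullLengthVerdict(rec.id, False, "no_orf")
            continue
        verdict = classify_full_length(len(rec.seq), orfs[0])
        verdicts[rec.id] = verdict
        if verdict.is_full_length:
            full.add(rec.id)
    return FullLengthCalls(full_length_ids=full, verdicts=verdicts)
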