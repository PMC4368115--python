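"""Readers and writers for the plain-text formats shared by all pipeline stages.

Supported formats: FASTA contig files, 12-column tabular homology hit files
(``outfmt 6`` layout), 9-column GTF with ``gene_id``/``transcript_id``
attributes, and TSV expression matrices (header row of tissue names, first
column of transcript ids).  Coordinates are kept 1-based inclusive at the GTF
boundary; interval arithmetic elsewhere converts to 0-based half-open.

Also provides :func:`format_fraction`, the half-up percentage formatter used
for every "n (x%)" style summary the reporting layers emit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FastaFormatError",
    "BlastFormatError",
    "GtfFormatError",
    "SequenceRecord",
    "HitRecord",
    "GtfFeature",
    "LocusModel",
    "FractionReport",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_gtf",
    "read_gtf_features",
    "group_loci",
    "write_gtf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "format_fraction",
    "round_half_up",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class FastaFormatError(FormatError):
    pass


class BlastFormatError(FormatError):
    pass


class GtfFormatError(FormatError):
    pass


_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with its identifier and free-text description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_seq(seq: str, rec_id: str, strict: bool) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        if strict:
            raise FastaFormatError(
                f"record {rec_id!r} contains invalid characters {sorted(bad)!r}"
            )
        logger.warning(
            "record %r: %d characters outside {A,C,G,T,N} mapped to N",
            rec_id,
            sum(seq.count(c) for c in bad),
        )
        table = str.maketrans({c: "N" for c in bad})
        seq = seq.translate(table)
    return seq


def read_fasta(path: str | Path, strict: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved.  Sequences are uppercased; characters outside
    ``{A,C,G,T,N}`` are mapped to ``N`` with a warning (rejected when
    ``strict``).  Duplicate ids are disambiguated with an ordinal suffix
    (``id.2``, ``id.3``, ...) and a warning — never silently overwritten.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise FastaFormatError(f"{path}: record with empty header line")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if not seq:
                raise FastaFormatError(f"{path}: record {rec_id!r} has empty sequence")
            if rec_id in seen:
                seen[rec_id] += 1
                new_id = f"{rec_id}.{seen[rec_id]}"
                logger.warning("duplicate FASTA id %r renamed to %r", rec_id, new_id)
                rec_id = new_id
            else:
                seen[rec_id] = 1
            records.append(
                SequenceRecord(id=rec_id, seq=_normalize_seq(seq, rec_id, strict), description=desc)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search result."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise BlastFormatError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value {self.evalue}"
            )


def read_blast_tab(path: str | Path, max_evalue: float = float("inf")) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table, keeping rows with
    ``evalue <= max_evalue``.  The number of excluded rows is logged."""
    path = Path(path)
    hits: list[HitRecord] = []
    excluded = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise BlastFormatError(
                    f"{path}: row {lineno} has {len(fields)} columns, expected 12"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise BlastFormatError(f"{path}: row {lineno}: {exc}") from exc
            if hit.evalue <= max_evalue:
                hits.append(hit)
            else:
                excluded += 1
    if excluded:
        logger.info("%s: excluded %d rows with E-value > %g", path, excluded, max_evalue)
    return hits


def write_blast_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )


_GTF_FEATURES = {"gene", "transcript", "exon"}
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GtfFeature:
    """One GTF row (gene, transcript, or exon); 1-based inclusive coordinates."""

    seqname: str
    source: str
    feature: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GtfFormatError(
                f"feature {self.gene_id}/{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.feature == "exon" and not self.transcript_id:
            raise GtfFormatError(f"exon of gene {self.gene_id} lacks transcript_id")


@dataclass
class LocusModel:
    """A gene locus: its transcripts as sorted exon-interval lists and the
    enclosing span, all 1-based inclusive on ``seqname``."""

    gene_id: str
    seqname: str
    strand: str
    span: tuple[int, int]
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_exons(self) -> int:
        return sum(len(exons) for exons in self.transcripts.values())


def read_gtf_features(path: str | Path) -> list[GtfFeature]:
    path = Path(path)
    feats: list[GtfFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfFormatError(f"{path}: line {lineno} has {len(fields)} columns, expected 9")
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                raise GtfFormatError(f"{path}: line {lineno} missing gene_id attribute")
            try:
                feats.append(
                    GtfFeature(
                        seqname=fields[0],
                        source=fields[1],
                        feature=fields[2],
                        start=int(fields[3]),
                        end=int(fields[4]),
                        strand=fields[6],
                        gene_id=attrs["gene_id"],
                        transcript_id=attrs.get("transcript_id", ""),
                    )
                )
            except ValueError as exc:
                raise GtfFormatError(f"{path}: line {lineno}: {exc}") from exc
    return feats


def group_loci(features: Sequence[GtfFeature]) -> list[LocusModel]:
    """Group features by ``gene_id`` into :class:`LocusModel` objects.

    Exon rows define transcripts; the locus span covers all its features.
    Order of first appearance is preserved.
    """
    loci: dict[str, LocusModel] = {}
    for feat in features:
        locus = loci.get(feat.gene_id)
        if locus is None:
            locus = LocusModel(
                gene_id=feat.gene_id,
                seqname=feat.seqname,
                strand=feat.strand,
                span=(feat.start, feat.end),
            )
            loci[feat.gene_id] = locus
        locus.span = (min(locus.span[0], feat.start), max(locus.span[1], feat.end))
        if feat.feature == "exon":
            locus.transcripts.setdefault(feat.transcript_id, []).append((feat.start, feat.end))
    for locus in loci.values():
        for exons in locus.transcripts.values():
            exons.sort()
    return list(loci.values())


def read_gtf(path: str | Path) -> list[LocusModel]:
    """Read a GTF file and return its features grouped into loci by gene_id."""
    return group_loci(read_gtf_features(path))


def write_gtf(loci: Iterable[LocusModel], path: str | Path, source: str = "troutatlas") -> None:
    with open(path, "w") as handle:
        for locus in loci:
            for tid, exons in locus.transcripts.items():
                for start, end in exons:
                    attrs = f'gene_id "{locus.gene_id}"; transcript_id "{tid}";'
                    handle.write(
                        "\t".join(
                            (
                                locus.seqname,
                                source,
                                "exon",
                                str(start),
                                str(end),
                                ".",
                                locus.strand,
                                ".",
                                attrs,
                            )
                        )
                        + "\n"
                    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: header row of tissue names, first column of ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def round_half_up(value: float | int | Decimal, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FractionReport:
    """An ``n (x%)`` style summary with declared half-up rounding."""

    numerator: int
    denominator: int
    percent: float
    decimals: int

    def __str__(self) -> str:
        return f"{self.numerator:,} ({self.percent:.{self.decimals}f}%)"


def format_fraction(numerator: int, denominator: int, decimals: int = 1) -> FractionReport:
    """Render ``numerator/denominator`` as a percentage rounded half-up.

    Raises ``ValueError`` when the denominator is zero.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if numerator < 0:
        raise ValueError(f"numerator must be non-negative, got {numerator}")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return FractionReport(
        numerator=numerator, denominator=denominator, percent=float(pct), decimals=decimals
    )
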