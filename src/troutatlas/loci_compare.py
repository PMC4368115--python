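"""Novel-locus detection against a genome annotation and splicing summaries.

A predicted locus is flagged as known in two fixed stages — nucleotide
homology of its transcripts to annotated mRNAs first, then coordinate
overlap of locus spans — and is novel only if both stages miss.  Novel sets
from genome mapping are merged with unmatched de novo contigs after
redundancy removal, and per-locus transcript/exon statistics summarize
alternative transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import HitRecord, LocusModel, SequenceRecord, round_half_up
from .orf_tools import classify_full_length, scan_orfs

__all__ = [
    "NovelLocusReport",
    "SpliceStats",
    "MergeResult",
    "flag_known_loci",
    "screen_novel_orfs",
    "merge_novel",
    "splice_stats",
    "transcripts_per_locus_mean",
]


@dataclass
class NovelLocusReport:
    """Partition of predicted locus ids into novel and the two known stages."""

    novel_ids: set[str]
    known_by_blast: set[str]
    known_by_overlap: set[str]
    orf_screen: dict[str, str]


def _spans_overlap(a: tuple[int, int], b: tuple[int, int], min_overlap_bp: int) -> bool:
    # 1-based inclusive spans; overlap length in bp
    return min(a[1], b[1]) - max(a[0], b[0]) + 1 >= min_overlap_bp


def flag_known_loci(
    predicted: Sequence[LocusModel],
    annotated: Sequence[LocusModel],
    blastn_hits: Sequence[HitRecord] = (),
    e_cutoff: float = 1e-5,
    stranded: bool = False,
    min_overlap_bp: int = 1,
) -> NovelLocusReport:
    """Classify predicted loci as known (by homology or by overlap) or novel.

    Stage 1: a locus is ``known_by_blast`` when any of its transcripts (or
    the locus id itself) appears as a query with ``evalue <= e_cutoff``.
    Stage 2: remaining loci are ``known_by_overlap`` when their span overlaps
    an annotated locus span on the same seqname by >= ``min_overlap_bp``
    (same strand additionally required when ``stranded``).  The three sets
    partition the predicted ids exactly.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    hit_queries = {h.query_id for h in blastn_hits if h.evalue <= e_cutoff}

    by_seqname: dict[str, list[LocusModel]] = {}
    for locus in annotated:
        by_seqname.setdefault(locus.seqname, []).append(locus)

    novel: set[str] = set()
    known_blast: set[str] = set()
    known_overlap: set[str] = set()
    for locus in predicted:
        if locus.gene_id in hit_queries or any(t in hit_queries for t in locus.transcripts):
            known_blast.add(locus.gene_id)
            continue
        candidates = by_seqname.get(locus.seqname, ())
        overlaps = any(
            _spans_overlap(locus.span, ann.span, min_overlap_bp)
            and (not stranded or locus.strand == ann.strand)
            for ann in candidates
        )
        if overlaps:
            known_overlap.add(locus.gene_id)
        else:
            novel.add(locus.gene_id)
    return NovelLocusReport(
        novel_ids=novel,
        known_by_blast=known_blast,
        known_by_overlap=known_overlap,
        orf_screen={},
    )


def screen_novel_orfs(
    novel: Iterable[str],
    sequences: Mapping[str, SequenceRecord],
    min_aa: int = 100,
) -> dict[str, str]:
    """Classify each novel locus as ``full_orf`` (interior ORF),
    ``partial_orf`` (best ORF fails the interior rule), or ``none``."""
    screen: dict[str, str] = {}
    for locus_id in novel:
        rec = sequences.get(locus_id)
        if rec is None:
            raise ValueError(f"no sequence available for novel locus {locus_id!r}")
        orfs = scan_orfs(rec, min_aa=min_aa)
        if not orfs:
            screen[locus_id] = "none"
            continue
        verdict = classify_full_length(len(rec.seq), orfs[0])
        screen[locus_id] = "full_orf" if verdict.is_full_length else "partial_orf"
    return screen


@dataclass
class MergeResult:
    combined_ids: set[str]
    n_novel_loci: int
    n_contigs_in: int
    n_contigs_surviving: int
    n_redundant_contigs: int


def merge_novel(
    novel_locus_ids: set[str],
    unmatched_contig_ids: set[str],
    redundancy_pairs: Sequence[tuple[str, str]] = (),
) -> MergeResult:
    """Union the novel loci with the unmatched contigs after dropping every
    contig named in a redundancy pair.

    Each pair is (novel locus id, contig id); a pair naming an id outside
    either input set is an error.
    """
    redundant: set[str] = set()
    for locus_id, contig_id in redundancy_pairs:
        if locus_id not in novel_locus_ids:
            raise ValueError(f"redundancy pair references unknown novel locus {locus_id!r}")
        if contig_id not in unmatched_contig_ids:
            raise ValueError(f"redundancy pair references unknown contig {contig_id!r}")
        redundant.add(contig_id)
    surviving = unmatched_contig_ids - redundant
    return MergeResult(
        combined_ids=novel_locus_ids | surviving,
        n_novel_loci=len(novel_locus_ids),
        n_contigs_in=len(unmatched_contig_ids),
        n_contigs_surviving=len(surviving),
        n_redundant_contigs=len(redundant),
    )


@dataclass
class SpliceStats:
    n_loci: int
    n_transcripts: int
    mean_transcripts_per_locus: float
    loci_ge_k: dict[int, int]
    n_exons: int
    mean_exons_per_locus: float


def transcripts_per_locus_mean(n_transcripts: int, n_loci: int, decimals: int = 2) -> float:
    """Mean transcripts per locus, rounded half-up."""
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    return round_half_up(n_transcripts / n_loci, decimals)


def splice_stats(
    loci: Sequence[LocusModel], k_values: Sequence[int] = (2, 5, 10)
) -> SpliceStats:
    """Per-locus transcript and exon summaries over a locus set.

    Means are totals over the locus count, rounded half-up to 2 decimals;
    ``loci_ge_k[k]`` counts loci with at least k transcripts (inclusive).
    """
    if not loci:
        raise ValueError("splice_stats requires a non-empty locus set")
    n_loci = len(loci)
    tx_counts = [locus.n_transcripts for locus in loci]
    n_transcripts = sum(tx_counts)
    n_exons = sum(locus.n_exons for locus in loci)
    return SpliceStats(
        n_loci=n_loci,
        n_transcripts=n_transcripts,
        mean_transcripts_per_locus=transcripts_per_locus_mean(n_transcripts, n_loci),
        loci_ge_k={k: sum(1 for c in tx_counts if c >= k) for k in k_values},
        n_exons=n_exons,
        mean_exons_per_locus=round_half_up(n_exons / n_loci, 2),
    )
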