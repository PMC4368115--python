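"""Post-assembly computations on de novo contig sets.

Length filtering and N50-style statistics, selection of one representative
transcript per contig component, proteome-coverage and reciprocal-unmatched
summaries of homology hit tables, and genome-alignment coverage tiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import FractionReport, HitRecord, SequenceRecord, format_fraction

__all__ = [
    "Contig",
    "AssemblyStats",
    "CoverageTierConfig",
    "contigs_from_records",
    "filter_by_length",
    "assembly_stats",
    "select_representatives",
    "proteome_coverage",
    "SpeciesCoverage",
    "ProteomeCoverageReport",
    "reciprocal_unmatched",
    "ReciprocalUnmatchedReport",
    "coverage_tiers",
]


@dataclass(frozen=True)
class Contig:
    """A contig with its component membership and best homology hit."""

    id: str
    component_id: str
    length: int
    has_hit: bool = False
    best_hit_subject: str = ""
    best_hit_evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1, got {self.length}")
        if self.has_hit != bool(self.best_hit_subject):
            raise ValueError(
                f"contig {self.id}: has_hit must be true iff best_hit_subject is non-empty"
            )


_TRINITY_COMPONENT_RE = re.compile(r"^(comp\d+|c\d+)")


def _component_of(contig_id: str, delimiter: str) -> str:
    m = _TRINITY_COMPONENT_RE.match(contig_id)
    if m:
        return m.group(1)
    return contig_id.split(delimiter, 1)[0]


def contigs_from_records(
    records: Sequence[SequenceRecord],
    hits: Sequence[HitRecord] = (),
    delimiter: str = "_",
) -> list[Contig]:
    """Build :class:`Contig` objects from FASTA records plus a hit table.

    The component id is the Trinity-style ``compX``/``cX`` prefix of the
    contig id, or the text before the first ``delimiter``.  The best hit per
    contig is the one with the lowest E-value (ties by bitscore descending,
    then subject id).
    """
    best: dict[str, HitRecord] = {}
    for hit in hits:
        prev = best.get(hit.query_id)
        if prev is None or (hit.evalue, -hit.bitscore, hit.subject_id) < (
            prev.evalue,
            -prev.bitscore,
            prev.subject_id,
        ):
            best[hit.query_id] = hit
    contigs = []
    for rec in records:
        hit = best.get(rec.id)
        contigs.append(
            Contig(
                id=rec.id,
                component_id=_component_of(rec.id, delimiter),
                length=len(rec.seq),
                has_hit=hit is not None,
                best_hit_subject=hit.subject_id if hit else "",
                best_hit_evalue=hit.evalue if hit else None,
            )
        )
    return contigs


def filter_by_length(
    contigs: Sequence[Contig], min_len: int = 500, strict: bool = False
) -> list[Contig]:
    """Retain contigs with ``length >= min_len`` (``> min_len`` when
    ``strict``), preserving input order."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if strict:
        return [c for c in contigs if c.length > min_len]
    return [c for c in contigs if c.length >= min_len]


@dataclass(frozen=True)
class AssemblyStats:
    n_bases: int
    n_contigs: int
    n50: int
    max_len: int
    min_len: int
    mean_len: float


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Summary statistics of a contig length set.

    N50 is the largest length L such that contigs of length >= L together
    hold at least half of all assembled bases; it is always the length of
    some contig in the set.
    """
    if not lengths:
        raise ValueError("assembly_stats requires a non-empty length set")
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum >= half:
            n50 = length
            break
    return AssemblyStats(
        n_bases=total,
        n_contigs=len(lengths),
        n50=n50,
        max_len=max(lengths),
        min_len=min(lengths),
        mean_len=total / len(lengths),
    )


def select_representatives(
    contigs: Sequence[Contig], drop_unique_singletons: bool = False
) -> set[str]:
    """Choose one representative contig id per gene group.

    Multi-contig components: the longest hit-bearing member (components with
    no hits contribute nothing).  Single-contig components with hits are
    grouped by best-hit subject and the longest per group is kept;
    ``drop_unique_singletons`` discards singleton groups with no competitor.
    Length ties break lexicographically by id.
    """
    by_component: dict[str, list[Contig]] = {}
    for contig in contigs:
        by_component.setdefault(contig.component_id, []).append(contig)

    reps: set[str] = set()
    singletons: list[Contig] = []
    for members in by_component.values():
        if len(members) > 1:
            with_hit = [c for c in members if c.has_hit]
            if with_hit:
                best = min(with_hit, key=lambda c: (-c.length, c.id))
                reps.add(best.id)
        else:
            contig = members[0]
            if contig.has_hit:
                singletons.append(contig)

    by_subject: dict[str, list[Contig]] = {}
    for contig in singletons:
        by_subject.setdefault(contig.best_hit_subject, []).append(contig)
    for group in by_subject.values():
        if len(group) == 1 and drop_unique_singletons:
            continue
        best = min(group, key=lambda c: (-c.length, c.id))
        reps.add(best.id)
    return reps


@dataclass(frozen=True)
class SpeciesCoverage:
    species: str
    n_subjects_hit: int
    fraction: FractionReport


@dataclass
class ProteomeCoverageReport:
    per_species: dict[str, SpeciesCoverage]
    queries_all_species: int
    queries_any_species: int
    n_queries: Optional[int] = None
    any_species_fraction: Optional[FractionReport] = None
    all_species_fraction: Optional[FractionReport] = None


def proteome_coverage(
    hits_by_species: Mapping[str, Sequence[HitRecord]],
    proteome_sizes: Mapping[str, int],
    e_cutoff: float = 1e-10,
    n_queries: Optional[int] = None,
    decimals: int = 2,
) -> ProteomeCoverageReport:
    """Per-species distinct-subject coverage plus cross-species query counts.

    For each species, counts distinct subject proteins hit at
    ``evalue <= e_cutoff`` against that species' proteome size.  Also counts
    queries hitting every species and queries hitting at least one; when
    ``n_queries`` is given those counts are additionally reported as
    fractions of the query set.
    """
    per_species: dict[str, SpeciesCoverage] = {}
    query_sets: list[set[str]] = []
    for species, hits in hits_by_species.items():
        if species not in proteome_sizes:
            raise ValueError(f"no proteome size given for species {species!r}")
        filtered = [h for h in hits if h.evalue <= e_cutoff]
        subjects = {h.subject_id for h in filtered}
        queries = {h.query_id for h in filtered}
        query_sets.append(queries)
        per_species[species] = SpeciesCoverage(
            species=species,
            n_subjects_hit=len(subjects),
            fraction=format_fraction(len(subjects), proteome_sizes[species], decimals),
        )
    if query_sets:
        all_species = set.intersection(*query_sets)
        any_species = set.union(*query_sets)
    else:
        all_species = set()
        any_species = set()
    report = ProteomeCoverageReport(
        per_species=per_species,
        queries_all_species=len(all_species),
        queries_any_species=len(any_species),
        n_queries=n_queries,
    )
    if n_queries is not None:
        report.any_species_fraction = format_fraction(len(any_species), n_queries, 1)
        report.all_species_fraction = format_fraction(len(all_species), n_queries, 1)
    return report


@dataclass
class ReciprocalUnmatchedReport:
    unmatched_a: set[str]
    unmatched_b: set[str]
    fraction_a: FractionReport
    fraction_b: FractionReport


def reciprocal_unmatched(
    hits_ab: Sequence[HitRecord],
    ids_a: set[str],
    hits_ba: Sequence[HitRecord],
    ids_b: set[str],
    e_cutoff: float = 1e-10,
    decimals: int = 1,
) -> ReciprocalUnmatchedReport:
    """Ids on each side with no qualifying hit against the other side.

    ``unmatched_a`` is ``ids_a`` minus queries with any hit at
    ``evalue <= e_cutoff`` in ``hits_ab``; symmetric for side b.
    """
    matched_a = {h.query_id for h in hits_ab if h.evalue <= e_cutoff}
    matched_b = {h.query_id for h in hits_ba if h.evalue <= e_cutoff}
    if not matched_a <= ids_a:
        raise ValueError("hits_ab contains query ids outside ids_a")
    if not matched_b <= ids_b:
        raise ValueError("hits_ba contains query ids outside ids_b")
    unmatched_a = ids_a - matched_a
    unmatched_b = ids_b - matched_b
    return ReciprocalUnmatchedReport(
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        fraction_a=format_fraction(len(unmatched_a), len(ids_a), decimals) if ids_a else
        format_fraction(0, 1, decimals),
        fraction_b=format_fraction(len(unmatched_b), len(ids_b), decimals) if ids_b else
        format_fraction(0, 1, decimals),
    )


@dataclass(frozen=True)
class CoverageTierConfig:
    tiers: tuple[float, ...] = (1.0, 0.9, 0.5)
    min_contig_len: int = 500
    hit_evalue_cutoff: float = 1e-10

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError("at least one tier required")
        if any(not 0 < t <= 1 for t in self.tiers):
            raise ValueError(f"tiers must be in (0, 1], got {self.tiers}")
        if any(a <= b for a, b in zip(self.tiers, self.tiers[1:])):
            raise ValueError(f"tiers must be strictly descending, got {self.tiers}")


def coverage_tiers(
    alignments: Sequence[tuple[str, float]],
    cfg: CoverageTierConfig = CoverageTierConfig(),
) -> dict[float, int]:
    """Count unique queries whose best-alignment coverage reaches each tier.

    A query counts in tier t when its coverage >= t, so counts are nested
    across descending tiers.
    """
    best: dict[str, float] = {}
    for query, cov in alignments:
        if not 0 <= cov <= 1:
            raise ValueError(f"coverage for {query!r} outside [0, 1]: {cov}")
        if cov > best.get(query, -1.0):
            best[query] = cov
    return {tier: sum(1 for cov in best.values() if cov >= tier) for tier in cfg.tiers}
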