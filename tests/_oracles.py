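"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own code paths: plain loops, naive
set algebra, and exhaustive scans only.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def orf_oracle(seq: str, min_aa: int, both_strands: bool = True) -> set[tuple[str, int, int]]:
    """All maximal ATG->stop ORFs as (strand, start, end), 1-based forward
    coordinates, by exhaustive candidate enumeration."""

    def strand_orfs(s: str) -> set[tuple[int, int]]:
        candidates = []
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(s):
                codon = s[j : j + 3]
                if "N" in codon:
                    break  # ORFs may not span an ambiguous codon
                if codon in STOPS:
                    if (j + 3 - i) // 3 - 1 >= min_aa:
                        candidates.append((i, j + 2))
                    break
                j += 3
        # maximal = no candidate in the same frame sharing the stop with an
        # earlier start
        maximal = set()
        for i, e in candidates:
            if not any(
                i2 < i and e2 == e and (i - i2) % 3 == 0 for i2, e2 in candidates
            ):
                maximal.add((i, e))
        return maximal

    n = len(seq)
    out = {("+", i + 1, e + 1) for i, e in strand_orfs(seq)}
    if both_strands:
        for i, e in strand_orfs(revcomp(seq)):
            out.add(("-", n - e, n - i))
    return out


def n50_oracle(lengths: list[int]) -> int:
    total = sum(lengths)
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum * 2 >= total:
            return length
    return 0


def representatives_oracle(contigs) -> set[str]:
    """Longest hit-bearing member per multi-contig component; longest per
    best-hit-subject group among singletons.  Ties break by id."""
    components: dict[str, list] = {}
    for c in contigs:
        components.setdefault(c.component_id, []).append(c)
    reps: set[str] = set()
    singleton_groups: dict[str, list] = {}
    for members in components.values():
        if len(members) == 1:
            c = members[0]
            if c.has_hit:
                singleton_groups.setdefault(c.best_hit_subject, []).append(c)
            continue
        best = None
        for c in members:
            if not c.has_hit:
                continue
            if best is None or c.length > best.length or (
                c.length == best.length and c.id < best.id
            ):
                best = c
        if best is not None:
            reps.add(best.id)
    for group in singleton_groups.values():
        best = group[0]
        for c in group[1:]:
            if c.length > best.length or (c.length == best.length and c.id < best.id):
                best = c
        reps.add(best.id)
    return reps


def tier_counts_oracle(alignments, tiers) -> dict[float, int]:
    best: dict[str, float] = {}
    for q, cov in alignments:
        if q not in best or cov > best[q]:
            best[q] = cov
    return {t: len([q for q, c in best.items() if c >= t]) for t in tiers}


def splice_stats_oracle(loci) -> dict:
    n_loci = 0
    n_tx = 0
    n_exons = 0
    tx_counts = []
    for locus in loci:
        n_loci += 1
        k = len(locus.transcripts)
        tx_counts.append(k)
        n_tx += k
        for exons in locus.transcripts.values():
            n_exons += len(exons)
    return {
        "n_loci": n_loci,
        "n_transcripts": n_tx,
        "n_exons": n_exons,
        "tx_counts": tx_counts,
    }


def intervals_overlap_oracle(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """1-based inclusive interval intersection by exhaustive point check on
    small intervals, else by the standard condition."""
    return max(a[0], b[0]) <= min(a[1], b[1])
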