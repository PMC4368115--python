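import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import n50_oracle, representatives_oracle, tier_counts_oracle
from troutatlas.assembly_post import (
    Contig,
    CoverageTierConfig,
    assembly_stats,
    contigs_from_records,
    coverage_tiers,
    filter_by_length,
    proteome_coverage,
    reciprocal_unmatched,
    select_representatives,
)
from troutatlas.io_formats import HitRecord
from troutatlas.synthgen import SimulationConfig, simulate_components


def contig(cid, comp, length, subject=""):
    return Contig(
        id=cid, component_id=comp, length=length,
        has_hit=bool(subject), best_hit_subject=subject,
        best_hit_evalue=1e-30 if subject else None,
    )


def hit(q, s, evalue=1e-30):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=95.0, aln_length=100, mismatches=2,
        gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
        evalue=evalue, bitscore=200.0,
    )


class TestFilterByLength:
    def test_inclusive_boundary(self):
        contigs = [contig(f"c{i}", f"k{i}", n) for i, n in enumerate([499, 500, 501])]
        assert [c.length for c in filter_by_length(contigs, 500)] == [500, 501]

    def test_strict_mode(self):
        contigs = [contig(f"c{i}", f"k{i}", n) for i, n in enumerate([499, 500, 501])]
        assert [c.length for c in filter_by_length(contigs, 500, strict=True)] == [501]

    def test_min_one_is_identity(self):
        contigs = [contig(f"c{i}", f"k{i}", n) for i, n in enumerate([3, 1, 7])]
        assert filter_by_length(contigs, 1) == contigs

    def test_random_matches_bruteforce(self, rng):
        lengths = rng.integers(1, 2000, size=1000)
        contigs = [contig(f"c{i}", f"k{i}", int(n)) for i, n in enumerate(lengths)]
        kept = filter_by_length(contigs, 500)
        assert [c.id for c in kept] == [c.id for c in contigs if c.length >= 500]


class TestAssemblyStats:
    def test_worked_example(self):
        stats = assembly_stats([5, 4, 3, 2, 1])
        assert stats.n50 == 4  # 5+4 = 9 >= 7.5
        assert stats.n_bases == 15
        assert stats.mean_len == 3.0

    def test_singleton(self):
        stats = assembly_stats([10])
        assert (stats.n50, stats.mean_len, stats.max_len, stats.min_len) == (10, 10.0, 10, 10)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    def test_random_matches_oracle(self, rng):
        for _ in range(50):
            lengths = [int(v) for v in rng.integers(1, 5000, size=int(rng.integers(1, 200)))]
            assert assembly_stats(lengths).n50 == n50_oracle(lengths)

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_invariants(self, lengths):
        stats = assembly_stats(lengths)
        assert stats.n50 in lengths
        assert stats.min_len <= stats.mean_len <= stats.max_len


class TestSelectRepresentatives:
    def test_longest_hit_bearing_member(self):
        members = [
            contig("a", "comp1", 700, "p1"),
            contig("b", "comp1", 900, "p1"),
            contig("c", "comp1", 950),  # no hit: not eligible
        ]
        assert select_representatives(members) == {"b"}

    def test_component_without_hits(self):
        members = [contig("a", "comp1", 700), contig("b", "comp1", 900)]
        assert select_representatives(members) == set()

    def test_singletons_grouped_by_subject(self):
        singles = [
            contig("s1", "compA", 600, "prot1"),
            contig("s2", "compB", 800, "prot1"),
            contig("s3", "compC", 700, "prot2"),
        ]
        assert select_representatives(singles) == {"s2", "s3"}

    def test_drop_unique_singletons(self):
        singles = [
            contig("s1", "compA", 600, "prot1"),
            contig("s2", "compB", 800, "prot1"),
            contig("s3", "compC", 700, "prot2"),
        ]
        assert select_representatives(singles, drop_unique_singletons=True) == {"s2"}

    def test_tie_breaks_lexicographically(self):
        members = [contig("zz", "comp1", 800, "p1"), contig("aa", "comp1", 800, "p1")]
        assert select_representatives(members) == {"aa"}

    def test_synthetic_truth(self, small_config):
        records, hits, truth = simulate_components(small_config)
        contigs = contigs_from_records(records, hits)
        assert select_representatives(contigs) == truth.representative_ids

    def test_random_matches_oracle(self, rng):
        for _ in range(30):
            contigs = []
            for i in range(int(rng.integers(1, 30))):
                size = int(rng.integers(1, 5))
                for j in range(size):
                    subject = f"p{int(rng.integers(5))}" if rng.random() < 0.7 else ""
                    contigs.append(
                        contig(f"c{i}_{j}", f"comp{i}", int(rng.integers(500, 3000)), subject)
                    )
            assert select_representatives(contigs) == representatives_oracle(contigs)

    def test_at_most_one_per_component_and_longest(self, rng):
        records, hits, _ = simulate_components(SimulationConfig(n_genes=200, seed=9))
        contigs = contigs_from_records(records, hits)
        reps = select_representatives(contigs)
        by_comp = {}
        for c in contigs:
            by_comp.setdefault(c.component_id, []).append(c)
        for comp, members in by_comp.items():
            if len(members) < 2:
                continue
            chosen = [c for c in members if c.id in reps]
            assert len(chosen) <= 1
            for c in chosen:
                assert all(c.length >= s.length for s in members if s.has_hit)


class TestProteomeCoverage:
    def test_single_species(self):
        hits = [hit("q1", "p1"), hit("q2", "p2"), hit("q3", "p1")]
        report = proteome_coverage({"sp": hits}, {"sp": 4}, decimals=2)
        cov = report.per_species["sp"]
        assert cov.n_subjects_hit == 2
        assert cov.fraction.percent == 50.00

    def test_no_hits(self):
        report = proteome_coverage({"sp": []}, {"sp": 10})
        assert report.per_species["sp"].n_subjects_hit == 0
        assert report.per_species["sp"].fraction.percent == 0.0
        assert report.queries_all_species == 0
        assert report.queries_any_species == 0

    def test_missing_proteome_size(self):
        with pytest.raises(ValueError):
            proteome_coverage({"sp": []}, {})

    def test_random_matches_set_algebra(self, rng):
        for _ in range(20):
            species = ["a", "b", "c"]
            tables = {
                sp: [
                    hit(f"q{int(rng.integers(30))}", f"{sp}_p{int(rng.integers(20))}",
                        evalue=float(10.0 ** -rng.uniform(0, 20)))
                    for _ in range(int(rng.integers(0, 60)))
                ]
                for sp in species
            }
            sizes = {sp: 20 for sp in species}
            report = proteome_coverage(tables, sizes, e_cutoff=1e-10)
            filtered = {sp: [h for h in tables[sp] if h.evalue <= 1e-10] for sp in species}
            for sp in species:
                assert report.per_species[sp].n_subjects_hit == len(
                    {h.subject_id for h in filtered[sp]}
                )
            qsets = [{h.query_id for h in filtered[sp]} for sp in species]
            assert report.queries_all_species == len(qsets[0] & qsets[1] & qsets[2])
            assert report.queries_any_species == len(qsets[0] | qsets[1] | qsets[2])


class TestReciprocalUnmatched:
    def test_simple_difference(self):
        report = reciprocal_unmatched([hit("x", "m1")], {"x", "y", "z"}, [], set())
        assert report.unmatched_a == {"y", "z"}

    def test_empty_tables(self):
        report = reciprocal_unmatched([], {"a", "b"}, [], {"c"})
        assert report.unmatched_a == {"a", "b"}
        assert report.unmatched_b == {"c"}

    def test_random_matches_set_difference(self, rng):
        for _ in range(30):
            ids_a = {f"a{i}" for i in range(int(rng.integers(1, 50)))}
            ids_b = {f"b{i}" for i in range(int(rng.integers(1, 50)))}
            hits_ab = [
                hit(f"a{int(rng.integers(len(ids_a)))}", "m",
                    evalue=float(10.0 ** -rng.uniform(0, 20)))
                for _ in range(int(rng.integers(0, 80)))
            ]
            report = reciprocal_unmatched(hits_ab, ids_a, [], ids_b, e_cutoff=1e-10)
            matched = {h.query_id for h in hits_ab if h.evalue <= 1e-10}
            assert report.unmatched_a == ids_a - matched
            assert report.unmatched_a & matched == set()

    def test_query_outside_id_set_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_unmatched([hit("stranger", "m")], {"x"}, [], set())


class TestCoverageTiers:
    def test_worked_example(self):
        alignments = [("q1", 1.0), ("q2", 0.95), ("q3", 0.6), ("q4", 0.3)]
        assert coverage_tiers(alignments) == {1.0: 1, 0.9: 2, 0.5: 3}

    def test_all_full_coverage(self):
        alignments = [(f"q{i}", 1.0) for i in range(7)]
        assert coverage_tiers(alignments) == {1.0: 7, 0.9: 7, 0.5: 7}

    def test_out_of_range_coverage(self):
        with pytest.raises(ValueError):
            coverage_tiers([("q", 1.2)])

    def test_tier_config_validation(self):
        with pytest.raises(ValueError):
            CoverageTierConfig(tiers=(0.5, 0.9))

    def test_random_matches_oracle_and_nested(self, rng):
        for _ in range(30):
            alignments = [
                (f"q{int(rng.integers(200))}", float(rng.random()))
                for _ in range(int(rng.integers(1, 300)))
            ]
            counts = coverage_tiers(alignments)
            assert counts == tier_counts_oracle(alignments, (1.0, 0.9, 0.5))
            assert counts[1.0] <= counts[0.9] <= counts[0.5]
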