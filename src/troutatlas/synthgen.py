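"""Synthetic inputs with known truth for every pipeline stage.

Emulates the 13-tissue non-normalized RNA-seq design: a genes x tissues
count matrix with planted housekeeping genes (expressed everywhere) and
planted tissue-specific genes (>= 8-fold over all other tissues), log-normal
baseline expression and transcript lengths, optional Poisson count noise;
multi-contig components with known longest members; contigs with embedded
ORFs at interior and boundary positions; and an annotated/predicted GTF pair
with planted novel loci.

All generators are pure functions of their configuration (seed included).
In noise-free expression mode the emitted integer counts are post-processed
so that exact RPKM recomputation plus the two classification rules recover
the planted labels with 100% precision and recall, including at rounding
edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .atlas import TISSUES, CountMatrix
from .io_formats import HitRecord, LocusModel, SequenceRecord

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_expression",
    "expected_counts",
    "simulate_components",
    "simulate_orf_contigs",
    "simulate_annotation_pair",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_tissues: int = 13
    frac_housekeeping: float = 0.05
    n_tissue_specific_per_tissue: int = 10
    fold_range: tuple[float, float] = (8.0, 40.0)
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    length_log_mean: float = 7.37  # ~1587 nt median
    length_log_sd: float = 0.4
    library_size: int = 10_000_000
    noise: str = "none"  # none | poisson
    seed: int = 0
    # annotation-pair extras
    n_annotated_loci: int = 50
    n_novel_loci: int = 10

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if not 0 <= self.frac_housekeeping <= 1:
            raise ValueError("frac_housekeeping must be a fraction")
        if self.fold_range[0] < 8:
            raise ValueError(
                f"fold_range low must be >= 8 so planted genes satisfy the rule, "
                f"got {self.fold_range[0]}"
            )
        if self.fold_range[0] > self.fold_range[1]:
            raise ValueError("fold_range must be (low, high) with low <= high")
        if self.noise not in {"none", "poisson"}:
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        n_planted = round(self.frac_housekeeping * self.n_genes) + (
            self.n_tissues * self.n_tissue_specific_per_tissue
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "fold_range" in data:
            data["fold_range"] = tuple(data["fold_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthLabels:
    """Ground-truth label sets for recovery tests."""

    housekeeping_ids: set[str] = field(default_factory=set)
    tissue_specific_ids: dict[str, set[str]] = field(default_factory=dict)
    novel_locus_ids: set[str] = field(default_factory=set)
    full_length_ids: set[str] = field(default_factory=set)
    representative_ids: set[str] = field(default_factory=set)


def _tissue_names(n: int) -> list[str]:
    if n <= len(TISSUES):
        return list(TISSUES[:n])
    return list(TISSUES) + [f"tissue{i}" for i in range(len(TISSUES), n)]


def _simulate_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    lengths = np.exp(rng.normal(cfg.length_log_mean, cfg.length_log_sd, size=n))
    return np.clip(np.rint(lengths), 500, 50_000).astype(np.int64)


def simulate_expression(
    config: SimulationConfig, noise_seed: Optional[int] = None
) -> tuple[CountMatrix, TruthLabels]:
    """Generate a count matrix with planted housekeeping and tissue-specific
    genes.

    With ``noise='none'`` counts are the rounded Poisson expectations,
    minimally adjusted so that the planted labels are exactly recoverable
    from the emitted integers; with ``noise='poisson'`` counts are Poisson
    draws around the continuous expectations.  ``noise_seed`` decouples the
    noise stream from the structural seed (replicate draws around one fixed
    expectation); by default both derive from ``config.seed``.
    """
    gene_ids, tissues, lengths, unit, rpkm, roles, focal, low_tissue, rng = _expression_structure(
        config
    )
    n_genes, n_tissues = config.n_genes, config.n_tissues
    lib = config.library_size

    expectation = rpkm * unit[:, None]
    if config.noise == "poisson":
        noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
        counts = noise_rng.poisson(expectation).astype(np.int64)
    else:
        counts = np.rint(expectation).astype(np.int64)
        _repair_noise_free(counts, roles, focal, low_tissue, unit, _TS_FOLD_RULE)

    truth = TruthLabels(
        housekeeping_ids={gene_ids[g] for g in range(n_genes) if roles[g] == "hk"},
        tissue_specific_ids={
            tissues[t]: {
                gene_ids[g] for g in range(n_genes) if roles[g] == "ts" and focal[g] == t
            }
            for t in range(n_tissues)
        },
    )
    cm = CountMatrix(
        gene_ids=gene_ids,
        tissue_ids=tissues,
        counts=counts,
        lengths=lengths,
        library_sizes=np.full(n_tissues, lib, dtype=np.int64),
    )
    return cm, truth


def expected_counts(config: SimulationConfig) -> np.ndarray:
    """The continuous Poisson-mean matrix (genes x tissues) behind
    :func:`simulate_expression` for this configuration."""
    _, _, _, unit, rpkm, *_ = _expression_structure(config)
    return rpkm * unit[:, None]


def _expression_structure(config: SimulationConfig):
    """Deterministic structural draw: ids, lengths, true RPKM, and roles."""
    rng = np.random.default_rng(config.seed)
    n_genes, n_tissues = config.n_genes, config.n_tissues
    tissues = _tissue_names(n_tissues)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    lengths = _simulate_lengths(rng, n_genes, config)
    lib = config.library_size
    unit = lengths.astype(float) * lib / 1e9  # counts per 1 RPKM, per gene

    n_hk = round(config.frac_housekeeping * n_genes)
    n_ts = config.n_tissue_specific_per_tissue
    roles = np.array(["bg"] * n_genes, dtype=object)
    focal = np.full(n_genes, -1)
    perm = rng.permutation(n_genes)
    roles[perm[:n_hk]] = "hk"
    pos = n_hk
    for t in range(n_tissues):
        idx = perm[pos : pos + n_ts]
        roles[idx] = "ts"
        focal[idx] = t
        pos += n_ts

    base = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_genes)
    rpkm = np.zeros((n_genes, n_tissues))
    low_tissue = np.full(n_genes, -1)
    for g in range(n_genes):
        if roles[g] == "hk":
            b = max(base[g], 3.0)
            rpkm[g] = b * rng.uniform(1.0, 3.0, size=n_tissues)
        elif roles[g] == "ts":
            row = base[g] * rng.uniform(0.25, 1.0, size=n_tissues)
            others = [t for t in range(n_tissues) if t != focal[g]]
            lt = int(rng.choice(others))
            row[lt] = rng.uniform(0.05, 0.4)
            fold = rng.uniform(*config.fold_range)
            row[focal[g]] = fold * max(row[t] for t in others)
            rpkm[g] = row
            low_tissue[g] = lt
        else:
            row = base[g] * rng.uniform(0.25, 1.0, size=n_tissues)
            lt = int(rng.integers(n_tissues))
            row[lt] = rng.uniform(0.05, 0.4)
            rpkm[g] = row
            low_tissue[g] = lt

    return gene_ids, tissues, lengths, unit, rpkm, roles, focal, low_tissue, rng


# the fold rule the repair pass enforces in count space; equal library
# sizes make RPKM ratios equal count ratios within a gene
_TS_FOLD_RULE = 8.0


def _repair_noise_free(
    counts: np.ndarray,
    roles: np.ndarray,
    focal: np.ndarray,
    low_tissue: np.ndarray,
    unit: np.ndarray,
    fold: float,
) -> None:
    """Adjust rounded noise-free counts in place so planted labels are
    exactly recoverable: housekeeping rows stay >= 1 RPKM everywhere,
    tissue-specific rows keep focal >= fold x max elsewhere, and no
    unplanted row satisfies either rule after integer rounding."""
    n_genes, n_tissues = counts.shape
    for g in range(n_genes):
        thr = unit[g]  # counts at exactly 1 RPKM
        if roles[g] == "hk":
            floor_hk = math.ceil(thr)
            counts[g] = np.maximum(counts[g], floor_hk)
            _break_ts(counts[g], fold, avoid=-1, min_allowed=floor_hk)
        else:
            lt = low_tissue[g]
            low_cap = math.floor(0.5 * thr)
            counts[g, lt] = min(counts[g, lt], low_cap)
            if roles[g] == "ts":
                f = focal[g]
                others = np.delete(counts[g], f)
                max_else = int(others.max()) if others.size else 0
                needed = max(1, math.ceil(fold * max_else))
                counts[g, f] = max(counts[g, f], needed)
            else:
                _break_ts(counts[g], fold, avoid=lt, min_allowed=0)


def _break_ts(row: np.ndarray, fold: float, avoid: int, min_allowed: int) -> None:
    """If the row accidentally satisfies the fold rule, raise its runner-up
    (never the tissue indexed ``avoid``) just above max/fold."""
    top = int(np.argmax(row))
    others = [t for t in range(len(row)) if t != top]
    if not others:
        return
    max_else = max(int(row[t]) for t in others)
    m1 = int(row[top])
    if m1 == 0 or (max_else > 0 and m1 < fold * max_else):
        return
    bump_to = max(math.floor(m1 / fold) + 1, min_allowed)
    candidates = [t for t in others if t != avoid]
    if candidates:
        t = max(candidates, key=lambda t: row[t])
        row[t] = max(int(row[t]), bump_to)
    else:
        # two-tissue corner: cannot bump without breaking the low tissue
        row[top] = max(0, math.floor(fold * max_else) - 1) if max_else else 0


_CODON_SAFE = ("GAA", "GAG", "GCT", "GCC", "GTT", "CTC", "CCT", "TCT", "CGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _flank(rng: np.random.Generator, n: int) -> str:
    # C/T-only flanks carry no start codon on either strand
    return "".join(rng.choice(["C", "T"], size=n))


def _orf_payload(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(rng.choice(_CODON_SAFE, size=n_aa))
    return "ATG" + body + "TAA"


def simulate_orf_contigs(
    config: SimulationConfig, min_aa: int = 100
) -> tuple[list[SequenceRecord], TruthLabels]:
    """Contigs with one embedded ORF each, cycling through four classes:
    interior (truth full-length), ORF at base 1, ORF ending at the last
    base, and no ORF.  Strand is randomized; flanks and codons are chosen so
    the planted ORF is the only one on either strand."""
    rng = np.random.default_rng(config.seed)
    classes = ("interior", "starts_at_first_base", "ends_at_last_base", "no_orf")
    records: list[SequenceRecord] = []
    truth = TruthLabels()
    for i in range(config.n_genes):
        klass = classes[i % len(classes)]
        cid = f"orfctg{i:05d}"
        n_aa = int(rng.integers(min_aa, min_aa + 50))
        payload = _orf_payload(rng, n_aa)
        if rng.random() < 0.5:
            payload = _rc(payload)
        left = _flank(rng, int(rng.integers(10, 100)))
        right = _flank(rng, int(rng.integers(10, 100)))
        if klass == "interior":
            seq = left + payload + right
            truth.full_length_ids.add(cid)
        elif klass == "starts_at_first_base":
            seq = payload + right
        elif klass == "ends_at_last_base":
            seq = left + payload
        else:
            seq = _flank(rng, len(payload))
        records.append(SequenceRecord(id=cid, seq=seq))
    return records, truth


def simulate_components(
    config: SimulationConfig, hit_prob: float = 0.7
) -> tuple[list[SequenceRecord], list[HitRecord], TruthLabels]:
    """Multi- and single-contig components with hit annotations.

    Within each multi-contig component member lengths are distinct, so
    exactly one contig is strictly longest among the hit-bearing members;
    that contig is the truth representative when the component has any hit.
    Singleton components draw their hit subjects from a small pool so that
    competing same-subject groups occur; the longest per group is truth.
    """
    rng = np.random.default_rng(config.seed)
    n_components = config.n_genes
    records: list[SequenceRecord] = []
    hits: list[HitRecord] = []
    truth = TruthLabels()
    singleton_groups: dict[str, list[tuple[int, str]]] = {}

    for i in range(n_components):
        multi = rng.random() < 0.4
        size = int(rng.integers(2, 7)) if multi else 1
        lengths = rng.choice(np.arange(500, 3000), size=size, replace=False)
        member_hits: list[tuple[str, int]] = []
        for j in range(size):
            cid = f"comp{i}_c0_seq{j}"
            length = int(lengths[j])
            seq = "".join(rng.choice(["A", "C", "G", "T"], size=length))
            records.append(SequenceRecord(id=cid, seq=seq))
            if rng.random() < hit_prob:
                if multi:
                    subject = f"sub{i}"
                else:
                    subject = f"ssub{int(rng.integers(max(1, n_components // 4)))}"
                    singleton_groups.setdefault(subject, []).append((length, cid))
                evalue = 10.0 ** -float(rng.uniform(15, 60))
                hits.append(
                    HitRecord(
                        query_id=cid,
                        subject_id=subject,
                        pct_identity=float(np.round(rng.uniform(70, 100), 2)),
                        aln_length=max(30, length // 3),
                        mismatches=int(rng.integers(0, 20)),
                        gap_opens=int(rng.integers(0, 4)),
                        q_start=1,
                        q_end=max(30, length // 3),
                        s_start=1,
                        s_end=max(30, length // 3),
                        evalue=evalue,
                        bitscore=float(np.round(rng.uniform(50, 2000), 1)),
                    )
                )
                if multi:
                    member_hits.append((cid, length))
        if multi and member_hits:
            best = min(member_hits, key=lambda ch: (-ch[1], ch[0]))
            truth.representative_ids.add(best[0])

    for group in singleton_groups.values():
        best = min(group, key=lambda lc: (-lc[0], lc[1]))
        truth.representative_ids.add(best[1])
    return records, hits, truth


def simulate_annotation_pair(
    config: SimulationConfig,
) -> tuple[list[LocusModel], list[LocusModel], TruthLabels]:
    """An annotated locus set plus a predicted set containing a jittered copy
    of every annotated locus and planted novel loci placed >= 1 kb away from
    any annotated span."""
    rng = np.random.default_rng(config.seed)
    annotated: list[LocusModel] = []
    predicted: list[LocusModel] = []
    truth = TruthLabels()

    def build_transcripts(rng, gene_id: str, span: tuple[int, int]) -> dict[str, list[tuple[int, int]]]:
        n_tx = min(int(rng.geometric(0.5)), 12)  # 1, 2, 3, ... with decaying mass
        txs: dict[str, list[tuple[int, int]]] = {}
        width = span[1] - span[0]
        for j in range(n_tx):
            n_exons = int(rng.integers(1, 9))
            cuts = np.sort(rng.choice(np.arange(width + 1), size=2 * n_exons, replace=False))
            exons = [
                (span[0] + int(cuts[2 * k]), span[0] + int(cuts[2 * k + 1]))
                for k in range(n_exons)
            ]
            txs[f"{gene_id}.t{j}"] = exons
        return txs

    cursor = 1
    novel_remaining = config.n_novel_loci
    slots = config.n_annotated_loci
    for i in range(slots):
        width = int(rng.integers(2000, 10_000))
        span = (cursor, cursor + width)
        gid = f"ANN{i:04d}"
        ann = LocusModel(
            gene_id=gid,
            seqname="chr1",
            strand="+" if rng.random() < 0.5 else "-",
            span=span,
            transcripts=build_transcripts(rng, gid, span),
        )
        annotated.append(ann)
        # predicted copy, jittered but always overlapping
        jitter = int(rng.integers(-500, 501))
        pspan = (max(1, span[0] + jitter), span[1] + int(rng.integers(-500, 501)))
        if pspan[1] <= pspan[0]:
            pspan = (pspan[0], pspan[0] + 100)
        pgid = f"PRED{i:04d}"
        predicted.append(
            LocusModel(
                gene_id=pgid,
                seqname="chr1",
                strand=ann.strand,
                span=pspan,
                transcripts=build_transcripts(rng, pgid, pspan),
            )
        )
        cursor = span[1] + 1500  # clear the jittered predicted copy too
        if novel_remaining > 0 and (slots - i <= novel_remaining or rng.random() < 0.4):
            nwidth = int(rng.integers(500, 2000))
            nspan = (cursor, cursor + nwidth)
            ngid = f"NOV{config.n_novel_loci - novel_remaining:04d}"
            predicted.append(
                LocusModel(
                    gene_id=ngid,
                    seqname="chr1",
                    strand="+" if rng.random() < 0.5 else "-",
                    span=nspan,
                    transcripts=build_transcripts(rng, ngid, nspan),
                )
            )
            truth.novel_locus_ids.add(ngid)
            novel_remaining -= 1
            cursor = nspan[1] + 1500
        else:
            cursor += 1500
    return annotated, predicted, truth
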