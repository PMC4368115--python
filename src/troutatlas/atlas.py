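"""RPKM normalization and housekeeping / tissue-specific classification.

The two classification rules, both with inclusive thresholds:

* housekeeping — RPKM >= ``hk_min_rpkm`` (default 1.0) in every tissue;
* tissue-specific — RPKM in one (focal) tissue >= ``ts_fold`` (default 8)
  times the maximum RPKM over all other tissues.  A positive focal value
  over an all-zero background qualifies (ratio treated as +infinity).

The rules do not logically exclude each other; any overlap between the two
classes is reported explicitly, never silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import read_matrix_tsv

__all__ = [
    "CountMatrix",
    "RpkmMatrix",
    "AtlasConfig",
    "AtlasClassification",
    "TISSUES",
    "compute_rpkm",
    "pool_replicates",
    "classify_housekeeping",
    "classify_tissue_specific",
    "atlas_report",
    "load_count_matrix",
]

#: The 13 tissues of the atlas design.
TISSUES = (
    "red_muscle",
    "skin",
    "fat",
    "brain",
    "gill",
    "spleen",
    "head_kidney",
    "liver",
    "stomach",
    "intestine",
    "testis",
    "white_muscle",
    "kidney",
)


@dataclass
class CountMatrix:
    """Mapped-read counts for genes x tissues, with transcript lengths (nt)
    and per-tissue library sizes (total mapped reads)."""

    gene_ids: list[str]
    tissue_ids: list[str]
    counts: np.ndarray  # (n_genes, n_tissues), non-negative integers
    lengths: np.ndarray  # (n_genes,), nt
    library_sizes: np.ndarray  # (n_tissues,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths)
        self.library_sizes = np.asarray(self.library_sizes)
        n_genes, n_tissues = len(self.gene_ids), len(self.tissue_ids)
        if self.counts.shape != (n_genes, n_tissues):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n_genes}, {n_tissues})"
            )
        if self.lengths.shape != (n_genes,):
            raise ValueError("lengths must have one entry per gene")
        if self.library_sizes.shape != (n_tissues,):
            raise ValueError("library_sizes must have one entry per tissue")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.size and (self.counts > self.library_sizes[None, :]).any():
            raise ValueError("counts cannot exceed the library size of their tissue")
        if n_genes and (self.lengths < 1).any():
            raise ValueError("transcript lengths must be >= 1")
        if n_tissues and (self.library_sizes < 1).any():
            raise ValueError("library sizes must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.tissue_ids)


@dataclass
class RpkmMatrix:
    """Normalized expression on the same axes as its source CountMatrix."""

    gene_ids: list[str]
    tissue_ids: list[str]
    rpkm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rpkm, index=self.gene_ids, columns=self.tissue_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RpkmMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            tissue_ids=[str(t) for t in frame.columns],
            rpkm=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class AtlasConfig:
    hk_min_rpkm: float = 1.0
    ts_fold: float = 8.0
    ts_focal_min_rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.ts_fold <= 1:
            raise ValueError(f"ts_fold must be > 1, got {self.ts_fold}")
        if self.hk_min_rpkm < 0:
            raise ValueError(f"hk_min_rpkm must be >= 0, got {self.hk_min_rpkm}")


@dataclass
class AtlasClassification:
    housekeeping: set[str]
    tissue_specific: dict[str, set[str]]
    overlap: set[str]


def compute_rpkm(cm: CountMatrix) -> RpkmMatrix:
    """RPKM[g, t] = counts[g, t] * 1e9 / (lengths[g] * library_sizes[t])."""
    if cm.shape[0] and (cm.lengths == 0).any():
        raise ValueError("zero transcript length")
    if cm.shape[1] and (cm.library_sizes == 0).any():
        raise ValueError("zero library size")
    rpkm = (
        cm.counts.astype(float)
        * 1e9
        / (cm.lengths[:, None].astype(float) * cm.library_sizes[None, :].astype(float))
    )
    return RpkmMatrix(gene_ids=list(cm.gene_ids), tissue_ids=list(cm.tissue_ids), rpkm=rpkm)


def pool_replicates(
    cms: Sequence[CountMatrix], grouping: Mapping[str, str]
) -> CountMatrix:
    """Sum replicate libraries into per-tissue columns.

    ``grouping`` maps a library column id to its tissue; counts and library
    sizes are summed within groups.  All inputs must share one gene axis.
    """
    if not cms:
        raise ValueError("pool_replicates requires at least one CountMatrix")
    genes = cms[0].gene_ids
    for cm in cms[1:]:
        if cm.gene_ids != genes:
            raise ValueError("all CountMatrix inputs must share the same gene axis")
        if not np.array_equal(cm.lengths, cms[0].lengths):
            raise ValueError("all CountMatrix inputs must share the same lengths")
    tissue_order: list[str] = []
    pooled_counts: dict[str, np.ndarray] = {}
    pooled_sizes: dict[str, int] = {}
    for cm in cms:
        for j, lib in enumerate(cm.tissue_ids):
            tissue = grouping.get(lib, lib)
            if tissue not in pooled_counts:
                tissue_order.append(tissue)
                pooled_counts[tissue] = np.zeros(len(genes), dtype=cm.counts.dtype)
                pooled_sizes[tissue] = 0
            pooled_counts[tissue] = pooled_counts[tissue] + cm.counts[:, j]
            pooled_sizes[tissue] += int(cm.library_sizes[j])
    return CountMatrix(
        gene_ids=list(genes),
        tissue_ids=tissue_order,
        counts=np.column_stack([pooled_counts[t] for t in tissue_order])
        if tissue_order
        else np.zeros((len(genes), 0), dtype=int),
        lengths=cms[0].lengths.copy(),
        library_sizes=np.array([pooled_sizes[t] for t in tissue_order], dtype=np.int64),
    )


def classify_housekeeping(rm: RpkmMatrix, cfg: AtlasConfig = AtlasConfig()) -> set[str]:
    """Genes with RPKM >= ``hk_min_rpkm`` in every tissue (inclusive)."""
    if rm.rpkm.size == 0:
        return set()
    keep = rm.rpkm.min(axis=1) >= cfg.hk_min_rpkm
    return {g for g, k in zip(rm.gene_ids, keep) if k}


def classify_tissue_specific(
    rm: RpkmMatrix, cfg: AtlasConfig = AtlasConfig()
) -> dict[str, set[str]]:
    """Genes whose focal-tissue RPKM is >= ``ts_fold`` times the maximum over
    all other tissues (inclusive; an all-zero background qualifies when the
    focal value is positive).  Sets are disjoint across tissues for any
    fold > 1."""
    n_genes, n_tissues = rm.rpkm.shape
    if n_tissues < 2:
        raise ValueError("classify_tissue_specific requires >= 2 tissues")
    result: dict[str, set[str]] = {t: set() for t in rm.tissue_ids}
    if n_genes == 0:
        return result
    x = rm.rpkm
    order = np.argsort(x, axis=1)
    top = order[:, -1]
    rows = np.arange(n_genes)
    top_val = x[rows, top]
    second_val = x[rows, order[:, -2]]
    qualifies = (top_val > 0) & (top_val >= cfg.ts_focal_min_rpkm)
    qualifies &= (second_val == 0) | (top_val >= cfg.ts_fold * second_val)
    for g in np.nonzero(qualifies)[0]:
        result[rm.tissue_ids[top[g]]].add(rm.gene_ids[g])
    return result


def atlas_report(rm: RpkmMatrix, cfg: AtlasConfig = AtlasConfig()) -> AtlasClassification:
    """Run both classifications and report their intersection explicitly."""
    hk = classify_housekeeping(rm, cfg)
    ts = classify_tissue_specific(rm, cfg)
    ts_all = set().union(*ts.values()) if ts else set()
    return AtlasClassification(housekeeping=hk, tissue_specific=ts, overlap=hk & ts_all)


def load_count_matrix(
    counts_path: str | Path, lengths_path: str | Path, libsizes_path: str | Path
) -> CountMatrix:
    """Assemble a CountMatrix from three TSV files: the counts matrix, a
    two-column (gene, length) table, and a two-column (tissue, size) table."""
    counts = read_matrix_tsv(counts_path)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    libsizes = pd.read_csv(libsizes_path, sep="\t", index_col=0).iloc[:, 0]
    lengths = lengths.reindex(counts.index)
    libsizes = libsizes.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError("lengths table missing entries for some genes")
    if libsizes.isna().any():
        raise ValueError("library-size table missing entries for some tissues")
    return CountMatrix(
        gene_ids=[str(g) for g in counts.index],
        tissue_ids=[str(t) for t in counts.columns],
        counts=counts.to_numpy(),
        lengths=lengths.to_numpy(),
        library_sizes=libsizes.to_numpy(),
    )
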