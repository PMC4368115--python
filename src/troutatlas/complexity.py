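"""Transcriptome complexity and composition metrics.

Per-tissue expressed-gene counts at a ladder of RPKM thresholds, cumulative
abundance curves (share of the mRNA pool held by the top-k genes),
tissue-specific mRNA fractions, and PCA coordinates for tissue clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import RpkmMatrix
from .io_formats import round_half_up

__all__ = [
    "ComplexityConfig",
    "AbundanceCurve",
    "expressed_counts",
    "cumulative_abundance",
    "tissue_specific_fraction",
    "tissue_pca",
]


@dataclass(frozen=True)
class ComplexityConfig:
    thresholds: tuple[float, ...] = (5.0, 1.0, 0.5, 0.1)
    abundance_threshold: float = 0.5
    total_gene_count: int = 0  # 0 means "use the matrix gene count"
    strict: bool = False  # strict=True counts RPKM strictly above each threshold

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be strictly descending, got {self.thresholds}")
        if self.abundance_threshold <= 0:
            raise ValueError("abundance_threshold must be positive")


def expressed_counts(
    rm: RpkmMatrix, cfg: ComplexityConfig = ComplexityConfig()
) -> pd.DataFrame:
    """Expressed-gene counts and fractions per tissue at each threshold.

    A gene counts as expressed at threshold t when RPKM >= t (inclusive).
    Returns a frame indexed by tissue with, per threshold, a ``count@t``
    column and a ``fraction@t`` column (count over the total gene count,
    rounded half-up to 2 decimals).
    """
    total = cfg.total_gene_count or len(rm.gene_ids)
    if total < len(rm.gene_ids):
        raise ValueError(
            f"total_gene_count {total} is smaller than the matrix gene count {len(rm.gene_ids)}"
        )
    if total == 0:
        raise ValueError("cannot compute fractions with zero genes")
    rows = {}
    for j, tissue in enumerate(rm.tissue_ids):
        col = rm.rpkm[:, j]
        row = {}
        for t in cfg.thresholds:
            count = int((col > t).sum() if cfg.strict else (col >= t).sum())
            row[f"count@{t:g}"] = count
            row[f"fraction@{t:g}"] = round_half_up(count / total, 2)
        rows[tissue] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class AbundanceCurve:
    """Cumulative share of a tissue's mRNA pool held by its top-k genes."""

    tissue: str
    ranks: np.ndarray
    cumulative_fraction: np.ndarray
    gene_ids: list[str]

    def at_rank(self, k: int) -> float:
        if not 1 <= k <= len(self.ranks):
            raise ValueError(f"rank {k} outside [1, {len(self.ranks)}]")
        return float(self.cumulative_fraction[k - 1])


def cumulative_abundance(rm: RpkmMatrix, tissue: str) -> AbundanceCurve:
    """Cumulative abundance curve for one tissue.

    Genes with RPKM > 0 are sorted descending (ties by gene id); entry k of
    the curve is the summed RPKM of the top k genes over the tissue total.
    """
    if tissue not in rm.tissue_ids:
        raise ValueError(f"unknown tissue {tissue!r}")
    col = rm.rpkm[:, rm.tissue_ids.index(tissue)]
    total = float(col.sum())
    if total <= 0:
        raise ValueError(f"tissue {tissue!r} has zero total RPKM")
    expressed = [(float(v), g) for v, g in zip(col, rm.gene_ids) if v > 0]
    expressed.sort(key=lambda vg: (-vg[0], vg[1]))
    values = np.array([v for v, _ in expressed])
    cum = np.cumsum(values) / total
    return AbundanceCurve(
        tissue=tissue,
        ranks=np.arange(1, len(values) + 1),
        cumulative_fraction=cum,
        gene_ids=[g for _, g in expressed],
    )


def tissue_specific_fraction(
    rm: RpkmMatrix,
    ts_sets: Mapping[str, set[str]],
    cfg: ComplexityConfig = ComplexityConfig(),
) -> dict[str, float]:
    """Share of each tissue's expressed mRNA pool held by its tissue-specific
    genes.

    The denominator sums RPKM over genes expressed in the tissue (RPKM >=
    ``abundance_threshold``); the numerator sums RPKM over the tissue's
    specific genes that are in that expressed universe.
    """
    gene_index = {g: i for i, g in enumerate(rm.gene_ids)}
    out: dict[str, float] = {}
    for j, tissue in enumerate(rm.tissue_ids):
        col = rm.rpkm[:, j]
        expressed = col >= cfg.abundance_threshold
        denom = float(col[expressed].sum())
        if denom <= 0:
            raise ValueError(f"tissue {tissue!r}: no expressed genes at threshold "
                             f"{cfg.abundance_threshold}")
        ts_genes = ts_sets.get(tissue, set())
        unknown = ts_genes - gene_index.keys()
        if unknown:
            raise ValueError(f"tissue {tissue!r}: unknown gene ids {sorted(unknown)[:3]}...")
        num = sum(float(col[gene_index[g]]) for g in ts_genes if expressed[gene_index[g]])
        out[tissue] = num / denom
    return out


def tissue_pca(rm: RpkmMatrix, n_components: int = 2) -> pd.DataFrame:
    """Tissue coordinates on the leading principal components of
    log2(RPKM + 1) expression.

    Genes are centered across tissues; tissue scores come from the singular
    value decomposition of the centered matrix (equivalent to the
    eigendecomposition of the tissue covariance).  Component signs are fixed
    by making the largest-magnitude gene loading positive.
    """
    n_genes, n_tissues = rm.rpkm.shape
    if n_tissues < 2 or n_genes < 2:
        raise ValueError("tissue_pca requires at least 2 genes and 2 tissues")
    x = np.log2(rm.rpkm + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # gene-wise centering
    if not np.any(np.abs(x) > 1e-12):
        raise ValueError("constant expression matrix: PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each gene-loading vector positive
    for k in range(len(s)):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    scores = (vt.T * s)[:, :n_components]
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return pd.DataFrame(scores, index=rm.tissue_ids, columns=cols)
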