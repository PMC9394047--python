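"""Ranking, decile windows, conserved/diverged gene sets, SNP-to-gene masks.

Orthologs are ranked by a divergence score (-log10 p for DE, -log10 FDR
for variability, corCor for co-expression), cut into ten even windows
(remainder genes dropped — 17,315 orthologs give 1731 per window), and the
top/bottom 10% become the diverged/conserved sets. For DE and variability
the TOP of the ranking is diverged; for corCor the top is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    GeneAnnotation,
    KeyingError,
    MarkerTable,
    ParameterError,
)

__all__ = [
    "METRIC_TOP_IS_DIVERGED",
    "ConservationPartition",
    "rank_genes",
    "assign_windows",
    "top_bottom_sets",
    "conservation_partition",
    "assign_markers",
]

#: orientation per metric: does the top of the ranking hold diverged genes?
METRIC_TOP_IS_DIVERGED = {
    "mean_expression_de": True,
    "variability": True,
    "corcor": False,
}


def rank_genes(scores: pd.Series, descending: bool = True) -> list[str]:
    """Total order of gene ids by score; ties break lexicographically by
    gene id; undefined (NaN) scores sink to the bottom."""
    s = scores.sort_index()  # lexicographic base order for stable ties
    arr = s.to_numpy(dtype=float)
    defined = ~np.isnan(arr)
    key = -arr if descending else arr
    order = np.argsort(np.where(defined, key, np.inf), kind="stable")
    return s.index[order].tolist()


def assign_windows(ranked, n_windows: int = 10) -> pd.Series:
    """Window index (1..n_windows) per gene; the n mod n_windows
    lowest-ranked genes are dropped (index pd.NA)."""
    ranked = list(ranked)
    n = len(ranked)
    w = n // n_windows
    if w < 1:
        raise ParameterError(f"{n} genes cannot fill {n_windows} windows")
    idx = np.full(n, 0, dtype=int)
    for i in range(n_windows):
        idx[i * w : (i + 1) * w] = i + 1
    out = pd.Series(idx, index=ranked, dtype="Int64")
    out[out == 0] = pd.NA
    return out


def top_bottom_sets(ranked, fraction: float = 0.10):
    """(top, bottom) gene sets of exactly floor(fraction * n) genes each.

    Which end is 'conserved' depends on the ranking metric; the caller
    makes that orientation explicit (see ``conservation_partition``).
    """
    if not (0 < fraction <= 0.5):
        raise ParameterError("fraction must be in (0, 0.5]")
    ranked = list(ranked)
    k = int(len(ranked) * fraction)
    if k < 1:
        raise ParameterError("fraction * n < 1; sets would be empty")
    return ranked[:k], ranked[-k:]


@dataclass
class ConservationPartition:
    """Ranked orthologs with windows and conserved/diverged membership."""

    tissue: str
    metric: str
    ranked: list
    window_index: pd.Series
    conserved_set: list
    diverged_set: list
    fraction: float


def conservation_partition(
    scores: pd.Series,
    metric: str,
    tissue: str = "",
    fraction: float = 0.10,
    n_windows: int = 10,
) -> ConservationPartition:
    """Build the full partition for one tissue and one conservation metric.

    ``scores`` is the per-gene ranking score (-log10 p, -log10 FDR, or
    corCor), ranked descending. Orientation follows the metric: for
    'mean_expression_de' and 'variability' the top of the ranking is
    diverged; for 'corcor' the top is conserved.
    """
    if metric not in METRIC_TOP_IS_DIVERGED:
        raise ParameterError(
            f"unknown metric {metric!r}; choose from {sorted(METRIC_TOP_IS_DIVERGED)}"
        )
    ranked = rank_genes(scores, descending=True)
    top, bottom = top_bottom_sets(ranked, fraction)
    if METRIC_TOP_IS_DIVERGED[metric]:
        diverged, conserved = top, bottom
    else:
        conserved, diverged = top, bottom
    return ConservationPartition(
        tissue=tissue,
        metric=metric,
        ranked=ranked,
        window_index=assign_windows(ranked, n_windows),
        conserved_set=conserved,
        diverged_set=diverged,
        fraction=fraction,
    )


def assign_markers(
    annotation: GeneAnnotation,
    markers: MarkerTable,
    gene_set,
    extension_bp: int = 50_000,
    genome_sizes: dict | None = None,
) -> np.ndarray:
    """Boolean mask over the genome-ordered marker table: True where the
    marker lies within ``extension_bp`` of any gene in ``gene_set``.

    Gene bodies are extended by ``extension_bp`` on both sides (the flank
    boundary is inclusive: a marker exactly ``extension_bp`` past a gene
    end is still captured), clamped at zero and, when ``genome_sizes`` is
    given, at the chromosome length. Overlapping windows are merged, so
    markers claimed by several genes count once.
    """
    if extension_bp < 0:
        raise ParameterError("extension_bp must be >= 0")
    ann = annotation.indexed()
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in ann.index]
    if missing:
        raise KeyingError(f"genes absent from annotation: {missing[:5]}")
    sub = ann.loc[gene_set]

    mask = np.zeros(len(markers), dtype=bool)
    mtab = markers.table
    for chrom, grp in sub.groupby("chrom", sort=False):
        starts = np.maximum(grp["start"].to_numpy() - extension_bp, 0)
        ends = grp["end"].to_numpy() + extension_bp
        if genome_sizes is not None and chrom in genome_sizes:
            ends = np.minimum(ends, genome_sizes[chrom])
        order = np.argsort(starts, kind="stable")
        merged_s, merged_e = [], []
        for s, e in zip(starts[order], ends[order]):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        on_chrom = (mtab["chrom"] == chrom).to_numpy()
        pos0 = mtab.loc[on_chrom, "pos"].to_numpy() - 1  # 1-based -> 0-based
        j = np.searchsorted(ms, pos0, side="right") - 1
        hit = (j >= 0) & (pos0 < me[np.clip(j, 0, None)])
        mask[np.flatnonzero(on_chrom)] = hit
    return mask
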