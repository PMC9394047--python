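"""GWAS-signal and chromatin-state enrichment for gene sets.

The GWAS statistic is T_sum = sum of squared single-marker effects b^2
over the markers assigned to a gene set. Its null distribution is built
by cyclical permutation: the genome-ordered effect vector is rotated by a
random offset while the marker mask stays fixed, which preserves the
local correlation structure of effects without needing genotypes. The
empirical one-tailed p is the proportion of rotated statistics at least
as large as the observed one (with a +1 pseudo-count by default so p is
never zero).

Chromatin-state enrichment around transcription start sites uses the
fold (C/A) / (B/D): C = bases of the state inside the TSS-window
universe, A = bases of the state genome-wide, B = bases in the window
universe, D = genome size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .io_formats import (
    ChromatinSegmentation,
    GeneAnnotation,
    KeyingError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "EnrichmentResult",
    "tsum",
    "cyclical_permutation_test",
    "hypergeometric_overlap",
    "chromatin_state_enrichment",
]


def tsum(effects_b: np.ndarray, mask) -> float:
    """T_sum = sum of b^2 over masked markers; 0 (with warning) if empty."""
    b = np.asarray(effects_b, dtype=float)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != b.shape:
            raise ValidationError("boolean mask length must match effect vector")
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(int)
        if len(idx) and (idx.min() < 0 or idx.max() >= len(b)):
            raise ValidationError("mask indexes outside the effect vector")
    if len(idx) == 0:
        warnings.warn("empty marker mask; T_sum = 0", stacklevel=2)
        return 0.0
    return float((b[idx] ** 2).sum())


@dataclass
class EnrichmentResult:
    """Outcome of one cyclical-permutation enrichment test."""

    t_sum_obs: float
    m_f: int
    n_perm: int
    p_empirical: float
    null_mean: float
    null_sd: float
    null_quantiles: dict
    seed: int | None
    null_sums: np.ndarray | None = field(default=None, repr=False)


def cyclical_permutation_test(
    effects_b: np.ndarray,
    mask,
    n_perm: int = 10_000,
    seed: int | None = None,
    pseudocount: bool = True,
    offsets=None,
    keep_null: bool = False,
) -> EnrichmentResult:
    """Enrichment of squared GWAS effects in a fixed marker mask.

    Each permutation rotates the genome-ordered effect vector by an offset
    drawn uniformly (with replacement) from 1..M-1 and recomputes T_sum
    against the unmoved mask. One-tailed p counts rotated statistics >=
    the observed one; with ``pseudocount`` (default) p = (1 + count) /
    (n_perm + 1), otherwise the pure proportion count / n_perm, which can
    be zero. Explicit ``offsets`` (e.g. every rotation including 0)
    override random sampling for exhaustive nulls.
    """
    b = np.asarray(effects_b, dtype=float)
    m = len(b)
    if m < 2:
        raise ParameterError("need >= 2 markers")
    b2 = b**2
    mask = np.asarray(mask)
    idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if len(idx) == 0:
        raise ParameterError("empty marker mask")
    t_obs = float(b2[idx].sum())

    if offsets is not None:
        offs = np.asarray(offsets, dtype=int)
    else:
        if n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        offs = rng.integers(1, m, size=n_perm)
    n_used = len(offs)

    if len(idx) == m:
        warnings.warn(
            "mask covers every marker; T_sum is rotation-invariant and p = 1",
            stacklevel=2,
        )
        null = np.full(n_used, t_obs)  # every rotation reorders the same sum
    else:
        # chunk the (n_perm x m_f) gather to bound memory on big masks
        null = np.empty(n_used)
        step = max(1, int(5e7) // max(len(idx), 1))
        for lo in range(0, n_used, step):
            chunk = offs[lo : lo + step]
            null[lo : lo + step] = b2[(idx[None, :] - chunk[:, None]) % m].sum(axis=1)

    count = int((null >= t_obs).sum())
    if pseudocount:
        p = (1 + count) / (n_used + 1)
    else:
        p = count / n_used
    qs = np.quantile(null, [0.0, 0.05, 0.5, 0.95, 1.0])
    return EnrichmentResult(
        t_sum_obs=t_obs,
        m_f=len(idx),
        n_perm=n_used,
        p_empirical=float(p),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_used > 1 else 0.0,
        null_quantiles={"min": qs[0], "q05": qs[1], "median": qs[2], "q95": qs[3], "max": qs[4]},
        seed=seed,
        null_sums=null if keep_null else None,
    )


def hypergeometric_overlap(overlap_k: int, set_a_size: int, set_b_size: int, universe_n: int) -> float:
    """Upper-tail hypergeometric overlap p-value, P(X >= k).

    X counts the overlap when ``set_b_size`` genes are drawn without
    replacement from a universe of ``universe_n`` containing
    ``set_a_size`` marked genes (R's phyper(k-1, A, N-A, B, lower=FALSE)).
    """
    if not (0 <= set_a_size <= universe_n and 0 <= set_b_size <= universe_n):
        raise ValidationError("set sizes must lie within the universe")
    if not (0 <= overlap_k <= min(set_a_size, set_b_size)):
        raise ValidationError("overlap must be <= both set sizes")
    return float(stats.hypergeom.sf(overlap_k - 1, universe_n, set_a_size, set_b_size))


def _merged_tss_windows(
    annotation: GeneAnnotation, gene_set, window_bp: int, genome_sizes: dict
) -> pd.DataFrame:
    ann = annotation.indexed()
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in ann.index]
    if missing:
        raise KeyingError(f"genes absent from annotation: {missing[:5]}")
    sub = ann.loc[gene_set]
    unknown = set(sub["chrom"]) - set(genome_sizes)
    if unknown:
        raise KeyingError(f"gene chromosomes missing from genome sizes: {sorted(unknown)[:5]}")
    tss = sub["start"].where(sub["strand"] == "+", sub["end"] - 1)
    lengths = sub["chrom"].map(genome_sizes)
    df = pd.DataFrame(
        {
            "Chromosome": sub["chrom"].to_numpy(),
            "Start": np.maximum(tss - window_bp, 0).to_numpy(),
            "End": np.minimum(tss + window_bp + 1, lengths).to_numpy(),
        }
    )
    return pr.PyRanges(df).merge().df


def chromatin_state_enrichment(
    seg: ChromatinSegmentation,
    annotation: GeneAnnotation,
    gene_set,
    window_bp: int = 2_000,
) -> pd.DataFrame:
    """Fold enrichment of every chromatin state in TSS +/- ``window_bp``.

    Windows around the TSS of each gene in ``gene_set`` (TSS base plus
    ``window_bp`` on both sides) are clamped to chromosome bounds and
    merged before counting, so B and C count unique bases. Returns one
    row per state with columns state, A, B, C, D, fold, fold_defined;
    fold = (C/A)/(B/D) and is NaN (flagged) when A = 0.
    """
    windows = _merged_tss_windows(annotation, gene_set, window_bp, seg.genome_sizes)
    b_bases = int((windows["End"] - windows["Start"]).sum())
    d_bases = int(sum(seg.genome_sizes.values()))

    iv = seg.intervals
    a_by_state = (iv["end"] - iv["start"]).groupby(iv["state"]).sum()

    seg_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": iv["chrom"].to_numpy(),
                "Start": iv["start"].to_numpy(),
                "End": iv["end"].to_numpy(),
                "State": iv["state"].to_numpy(),
            }
        )
    )
    hits = seg_pr.intersect(pr.PyRanges(windows)).df
    if len(hits):
        c_by_state = (hits["End"] - hits["Start"]).groupby(hits["State"]).sum()
    else:
        c_by_state = pd.Series(dtype=int)

    rows = []
    for state in sorted(a_by_state.index):
        a = int(a_by_state[state])
        c = int(c_by_state.get(state, 0))
        if a > 0 and d_bases > 0 and b_bases > 0:
            fold = (c / a) / (b_bases / d_bases)
            defined = True
        else:
            fold = np.nan
            defined = False
        rows.append((state, a, b_bases, c, d_bases, fold, defined))
    return pd.DataFrame(
        rows, columns=["state", "A", "B", "C", "D", "fold", "fold_defined"]
    )
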