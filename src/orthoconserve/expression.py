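"""Mean-expression conservation: tissue summaries, tissue specificity,
between-species differential expression, decile window overlap, clustering.

All log-scale statistics use log2(TPM + 0.25); species-level differential
expression uses a Welch two-sample t-test on that scale with
Benjamini-Hochberg FDR, flagging genes at |log2FC| > log2(1.2) and
FDR < 0.05; tissue-specific expression uses a one-vs-rest contrast flagged
at log2FC > 1.5 (upregulation in the target tissue) and FDR < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import cluster, spatial, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    ExpressionMatrix,
    KeyingError,
    OrthologMap,
    ParameterError,
    ValidationError,
)

__all__ = [
    "LOG_OFFSET",
    "EXPRESSED_TPM_THRESHOLD",
    "SPECIES_DE_LOG2FC",
    "TISSUE_DE_LOG2FC",
    "DE_FDR",
    "log_transform",
    "tissue_summary",
    "count_expressed",
    "shared_window_fraction",
    "tau_score",
    "welch_ttest",
    "differential_expression",
    "tissue_specific_de",
    "bh_fdr",
    "cluster_tissues",
]

#: pseudo-count added before log2, matching the scale the analysis runs on
LOG_OFFSET = 0.25
#: a gene counts as expressed in a tissue when its median TPM exceeds this
EXPRESSED_TPM_THRESHOLD = 0.1
#: between-species DE flag: |log2FC| > log2(1.2) and FDR < DE_FDR
SPECIES_DE_LOG2FC = float(np.log2(1.2))
#: tissue-specific flag: log2FC > 1.5 (target above rest) and FDR < DE_FDR
TISSUE_DE_LOG2FC = 1.5
DE_FDR = 0.05

_TINY = float(np.finfo(float).tiny)


def log_transform(tpm):
    """log2(TPM + 0.25); raises on negative input."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValidationError("TPM must be non-negative")
    out = np.log2(arr + LOG_OFFSET)
    return float(out) if np.ndim(tpm) == 0 else out


def tissue_summary(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-(gene, tissue) summary statistics.

    Returns a tidy DataFrame with columns gene_id, tissue, median_tpm,
    mean_log2, mad_log2, cv, cv_defined, expressed, n_samples. MAD is the
    unscaled median absolute deviation of log2(TPM+0.25); CV is sd/mean of
    linear TPM (ddof=1), undefined (NaN, cv_defined=False) when the mean
    is zero.
    """
    frames = []
    for tissue in expr.tissues:
        sub = expr.subset_tissue(tissue)
        if sub.shape[1] < 2:
            raise ValidationError(
                f"tissue {tissue!r} has {sub.shape[1]} sample(s); need >= 2"
            )
        tpm = sub.values.to_numpy(dtype=float)
        log2 = np.log2(tpm + LOG_OFFSET)
        median_tpm = np.median(tpm, axis=1)
        mean_log2 = log2.mean(axis=1)
        mad_log2 = np.median(
            np.abs(log2 - np.median(log2, axis=1, keepdims=True)), axis=1
        )
        mean_lin = tpm.mean(axis=1)
        sd_lin = tpm.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean_lin > 0, sd_lin / mean_lin, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.gene_ids,
                    "tissue": tissue,
                    "median_tpm": median_tpm,
                    "mean_log2": mean_log2,
                    "mad_log2": mad_log2,
                    "cv": cv,
                    "cv_defined": mean_lin > 0,
                    "expressed": median_tpm > EXPRESSED_TPM_THRESHOLD,
                    "n_samples": sub.shape[1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def count_expressed(summary: pd.DataFrame, tissue: str) -> int:
    """Number of genes expressed (median TPM > 0.1) in a tissue."""
    sub = summary[summary["tissue"] == tissue]
    if sub.empty:
        raise KeyingError(f"unknown tissue {tissue!r}")
    return int(sub["expressed"].sum())


def shared_window_fraction(ranked_a, ranked_b, n_windows: int = 10) -> pd.DataFrame:
    """Percentage of genes shared per rank window between two rankings.

    Both rankings must be permutations of the same gene set. Genes are cut
    into ``n_windows`` even windows of size floor(n / n_windows) from the
    top of each ranking; the ``n mod n_windows`` lowest-ranked genes are
    dropped. Returns columns window (1-based), window_size, n_shared,
    overlap_pct.
    """
    a = list(ranked_a)
    b = list(ranked_b)
    if set(a) != set(b) or len(a) != len(set(a)) or len(b) != len(set(b)):
        raise ValidationError("rankings must be permutations of the same gene set")
    n = len(a)
    w = n // n_windows
    if w < 1:
        raise ParameterError(f"{n} genes cannot fill {n_windows} windows")
    rows = []
    for i in range(n_windows):
        wa = set(a[i * w : (i + 1) * w])
        wb = set(b[i * w : (i + 1) * w])
        shared = len(wa & wb)
        rows.append((i + 1, w, shared, 100.0 * shared / w))
    return pd.DataFrame(rows, columns=["window", "window_size", "n_shared", "overlap_pct"])


def tau_score(values) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (N - 1) over per-tissue expression
    values (here: per-tissue median TPM). 0 marks ubiquitous expression,
    1 a single-tissue gene. Raises for all-zero or negative input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("tau needs a 1-d vector of >= 2 tissues")
    if (x < 0).any():
        raise ValidationError("tau input must be non-negative")
    xmax = x.max()
    if xmax == 0:
        raise ValidationError("tau undefined for an all-zero profile")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))


def welch_ttest(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t-test between two matrices (genes x samples).

    Returns (t, p, degenerate) where ``degenerate`` flags rows with zero
    variance on both sides: equal means give t=0, p=1; unequal means give
    p equal to the smallest positive float (keeps the ranking total) with
    a sign-carrying infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.shape[1], b.shape[1]
    if n < 2 or m < 2:
        raise ParameterError("Welch test needs >= 2 samples per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / n + vb / m
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / m) ** 2 / (m - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        eq = degenerate & (ma == mb)
        ne = degenerate & (ma != mb)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.where(ma[ne] > mb[ne], np.inf, -np.inf)
        p[ne] = _TINY
        if ne.any():
            warnings.warn(
                f"{int(ne.sum())} gene(s) with zero variance in both groups and "
                "unequal means; p set to the smallest positive float",
                stacklevel=2,
            )
    return t, np.clip(p, 0.0, 1.0), degenerate


def differential_expression(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orthologs: OrthologMap,
) -> pd.DataFrame:
    """Between-species DE over ortholog pairs on log2(TPM+0.25).

    ``expr_a`` / ``expr_b`` are typically already restricted to one tissue.
    log2fc is mean(A) - mean(B) on the log scale; the significance flag
    requires |log2fc| > log2(1.2) and BH FDR < 0.05. Returns one row per
    ortholog pair: gene_a, gene_b, log2fc, t_stat, p, fdr, direction,
    significant, degenerate.
    """
    a = expr_a.subset_genes(orthologs.a_ids).values.to_numpy(dtype=float)
    b = expr_b.subset_genes(orthologs.b_ids).values.to_numpy(dtype=float)
    la, lb = np.log2(a + LOG_OFFSET), np.log2(b + LOG_OFFSET)
    t, p, degenerate = welch_ttest(la, lb)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    fdr = bh_fdr(p)
    out = pd.DataFrame(
        {
            "gene_a": orthologs.a_ids,
            "gene_b": orthologs.b_ids,
            "log2fc": log2fc,
            "t_stat": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up_in_a", np.where(log2fc < 0, "up_in_b", "none")),
            "significant": (np.abs(log2fc) > SPECIES_DE_LOG2FC) & (fdr < DE_FDR),
            "degenerate": degenerate,
        }
    )
    return out


def tissue_specific_de(expr: ExpressionMatrix, tissue: str) -> pd.DataFrame:
    """One-vs-rest DE for one tissue on log2(TPM+0.25).

    The flag requires upregulation in the target tissue: log2fc > 1.5 and
    BH FDR < 0.05.
    """
    in_t = (expr.tissue_of_sample == tissue).to_numpy()
    if not in_t.any():
        raise KeyingError(f"unknown tissue {tissue!r}")
    if in_t.sum() < 2 or (~in_t).sum() < 2:
        raise ValidationError(f"tissue {tissue!r} and rest both need >= 2 samples")
    tpm = expr.values.to_numpy(dtype=float)
    log2 = np.log2(tpm + LOG_OFFSET)
    t, p, degenerate = welch_ttest(log2[:, in_t], log2[:, ~in_t])
    log2fc = log2[:, in_t].mean(axis=1) - log2[:, ~in_t].mean(axis=1)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "tissue": tissue,
            "log2fc": log2fc,
            "t_stat": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up_in_tissue", np.where(log2fc < 0, "down_in_tissue", "none")),
            "significant": (log2fc > TISSUE_DE_LOG2FC) & (fdr < DE_FDR),
            "degenerate": degenerate,
        }
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def cluster_tissues(profile: pd.DataFrame):
    """Hierarchical clustering of tissues by expression profile.

    ``profile`` is tissues x genes (e.g. per-tissue median TPM or MAD).
    Distance is 1 - Pearson correlation; linkage is complete. Rows are
    sorted by label first so ties resolve by label order. Returns
    (linkage_matrix, labels) in scipy ``linkage`` convention.
    """
    if profile.shape[0] < 2:
        raise ParameterError("need >= 2 tissues to cluster")
    profile = profile.sort_index()
    arr = profile.to_numpy(dtype=float)
    constant = arr.std(axis=1) == 0
    if constant.any():
        bad = profile.index[constant].tolist()
        raise ValidationError(f"constant profile for tissue(s): {bad}")
    dist = spatial.distance.pdist(arr, metric="correlation")
    linkage = cluster.hierarchy.linkage(dist, method="complete")
    return linkage, profile.index.tolist()
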