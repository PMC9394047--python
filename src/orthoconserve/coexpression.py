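"""Co-expression conservation.

corCor measures how well a gene's co-expression neighbourhood is preserved
between two expression matrices over the same (ortholog-aligned) genes:
for gene g, take the Spearman correlations of g with the other n-1 genes
in each matrix (vectors A and A', same gene order) and report their
Pearson correlation. Soft connectivity k_i = sum_j |r_ij|^beta is the
weighted network degree used to compare module wiring across species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ParameterError, ValidationError

__all__ = [
    "SCENARIOS",
    "corcor",
    "soft_connectivity",
    "connectivity_correlation",
]

SCENARIOS = (
    "between-tissues-within-A",
    "between-tissues-within-B",
    "within-tissue-between-species",
)


def _as_matrix(expr) -> tuple[np.ndarray, pd.Index]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), expr.index
    arr = np.asarray(expr, dtype=float)
    return arr, pd.Index(range(arr.shape[0]))


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Gene x gene Spearman correlation (average ranks for ties)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    with np.errstate(invalid="ignore"):
        return np.corrcoef(ranks)


def _row_pearson(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired rows of two matrices."""
    uc = u - u.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    num = (uc * vc).sum(axis=1)
    den = np.sqrt((uc**2).sum(axis=1) * (vc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def corcor(
    expr_1,
    expr_2,
    gene_order=None,
    scenario: str = "within-tissue-between-species",
) -> pd.DataFrame:
    """Per-gene correlation-of-correlations between two matrices.

    ``expr_1`` and ``expr_2`` are genes x samples (DataFrame or array)
    over the same aligned genes — for the cross-species scenario, rows
    are ortholog pairs in matching order. ``gene_order`` names the rows
    (defaults to expr_1's index). Genes constant in either matrix are
    excluded from all correlation vectors and flagged. Returns columns
    gene_id, corcor, flagged, scenario, n_genes_in_background.
    """
    m1, idx1 = _as_matrix(expr_1)
    m2, _ = _as_matrix(expr_2)
    if m1.shape[0] != m2.shape[0]:
        raise ValidationError("matrices must cover the same aligned genes")
    if m1.shape[1] < 4 or m2.shape[1] < 4:
        raise ParameterError("corCor needs >= 4 samples per matrix")
    genes = pd.Index(gene_order) if gene_order is not None else idx1
    if len(genes) != m1.shape[0]:
        raise ValidationError("gene_order length mismatch")

    ok = (m1.std(axis=1) > 0) & (m2.std(axis=1) > 0)
    vals = np.full(len(genes), np.nan)
    n_bg = int(ok.sum())
    if n_bg >= 3:
        r1 = _spearman_matrix(m1[ok])
        r2 = _spearman_matrix(m2[ok])
        v = r1.shape[0]
        off = ~np.eye(v, dtype=bool)
        # vectors of length v-1: each gene against the others, self excluded
        a = r1[off].reshape(v, v - 1)
        a2 = r2[off].reshape(v, v - 1)
        vals[np.flatnonzero(ok)] = _row_pearson(a, a2)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "corcor": vals,
            "flagged": ~ok | np.isnan(vals),
            "scenario": scenario,
            "n_genes_in_background": n_bg,
        }
    )


def soft_connectivity(expr, beta: int = 6) -> pd.Series:
    """Per-gene soft connectivity k_i = sum_{j != i} |pearson r_ij|^beta.

    Constant genes get NaN connectivity and do not contribute to other
    genes' sums.
    """
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    m, genes = _as_matrix(expr)
    if m.shape[1] < 4:
        raise ParameterError("soft connectivity needs >= 4 samples")
    ok = m.std(axis=1) > 0
    k = np.full(m.shape[0], np.nan)
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(m[ok])
        a = np.abs(r) ** beta
        np.fill_diagonal(a, 0.0)
        k[np.flatnonzero(ok)] = a.sum(axis=1)
    elif ok.sum() == 1:
        k[np.flatnonzero(ok)] = 0.0
    return pd.Series(k, index=genes, name="connectivity")


def connectivity_correlation(k_a: pd.Series, k_b: pd.Series, gene_set) -> float:
    """Pearson correlation of two connectivity vectors over a gene set."""
    genes = pd.Index(gene_set)
    if len(genes) < 3:
        raise ParameterError("need >= 3 genes")
    missing = genes.difference(k_a.index).union(genes.difference(k_b.index))
    if len(missing):
        raise ValidationError(f"connectivity undefined for: {missing.tolist()[:5]}")
    a = k_a.loc[genes].to_numpy(dtype=float)
    b = k_b.loc[genes].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("connectivity contains flagged (NaN) members")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant connectivity vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
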