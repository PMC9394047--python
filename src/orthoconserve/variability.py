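"""Differential variability of gene expression between species.

For each ortholog pair within a tissue, the variance ratio
f = s1^2 / s2^2 of log2(TPM+0.25) values is referred to an
F(n-1, m-1) distribution (n, m sample counts of the two species).
Sidedness is two-sided: p = min(1, 2 * min(lower tail, upper tail)).
Genes are ranked downstream by -log10(FDR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import LOG_OFFSET, bh_fdr
from .io_formats import ExpressionMatrix, OrthologMap, ParameterError

__all__ = ["differential_variability", "differential_variability_table"]

_TINY = float(np.finfo(float).tiny)


def differential_variability(x_a, x_b):
    """Two-sided F-test for equal variances of two log2-expression vectors.

    Returns ``(f, p)``; f = s1^2/s2^2 with n-1 denominator variances.
    Degenerate cases: s2^2 = 0 with s1^2 > 0 gives (inf, tiny);
    both variances zero gives (nan, 1.0).
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need >= 2 samples per group")
    f, p = _ftest_rows(a[None, :], b[None, :])
    return float(f[0]), float(p[0])


def _ftest_rows(a: np.ndarray, b: np.ndarray):
    """Vectorised two-sided variance-ratio F-test over rows."""
    n, m = a.shape[1], b.shape[1]
    s1 = a.var(axis=1, ddof=1)
    s2 = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = s1 / s2
    dist = stats.f(n - 1, m - 1)
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * np.minimum(dist.cdf(f), dist.sf(f)))
    only_b_zero = (s2 == 0) & (s1 > 0)
    both_zero = (s2 == 0) & (s1 == 0)
    only_a_zero = (s1 == 0) & (s2 > 0)
    f[only_b_zero], p[only_b_zero] = np.inf, _TINY
    f[both_zero], p[both_zero] = np.nan, 1.0
    p[only_a_zero] = _TINY  # f = 0 exactly; maximally lower-tailed
    return f, p


def differential_variability_table(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orthologs: OrthologMap,
) -> pd.DataFrame:
    """Per-ortholog differential variability within a tissue.

    Inputs are TPM matrices (typically one tissue per species); the test
    runs on log2(TPM+0.25). Columns: gene_a, gene_b, s1_sq, s2_sq, f, n,
    m, p, fdr, degenerate (any zero sample variance).
    """
    a = expr_a.subset_genes(orthologs.a_ids).values.to_numpy(dtype=float)
    b = expr_b.subset_genes(orthologs.b_ids).values.to_numpy(dtype=float)
    la, lb = np.log2(a + LOG_OFFSET), np.log2(b + LOG_OFFSET)
    if la.shape[1] < 2 or lb.shape[1] < 2:
        raise ParameterError("need >= 2 samples per species")
    f, p = _ftest_rows(la, lb)
    s1 = la.var(axis=1, ddof=1)
    s2 = lb.var(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "gene_a": orthologs.a_ids,
            "gene_b": orthologs.b_ids,
            "s1_sq": s1,
            "s2_sq": s2,
            "f": f,
            "n": la.shape[1],
            "m": lb.shape[1],
            "p": p,
            "fdr": bh_fdr(p),
            "degenerate": (s1 == 0) | (s2 == 0),
        }
    )
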