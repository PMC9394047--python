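# orthoconserve

Cross-species comparison of transcriptomes asks a simple question with a
long pipeline behind it: across the one-to-one orthologs two species
share, which genes keep the same expression behaviour — level,
inter-individual variability, co-expression neighbourhood — and do the
conserved ones carry more of the genetic signal of complex traits?
`orthoconserve` implements that pipeline end to end for paired bulk
expression resources (e.g. a human and a livestock expression atlas over
common tissues), with a seeded synthetic-data generator so every stage
can be validated against known ground truth without any downloads.

It is aimed at comparative genomicists and quantitative geneticists who
have: two gene × sample TPM matrices with tissue labels, a one-to-one
ortholog map, a gene annotation, genome-ordered GWAS summary effects,
and (optionally) a chromatin segmentation.

## What it computes

* **Tissue summaries** — per (gene, tissue): median TPM, MAD and mean of
  log2(TPM+0.25), CV of linear TPM, expressed flag (median TPM > 0.1).
* **Tissue specificity** — the τ index,
  τ = Σᵢ (1 − xᵢ/x_max)/(N−1) over per-tissue medians, and one-vs-rest
  differential expression (Welch t on log2(TPM+0.25); flagged at
  log2FC > 1.5, BH FDR < 0.05).
* **Between-species differential expression** — per ortholog pair,
  Welch t on log2(TPM+0.25) within a tissue, flagged at |log2FC| >
  log2(1.2) and FDR < 0.05.
* **Differential variability** — the variance-ratio test f = s₁²/s₂²
  referred to F(n−1, m−1), two-sided, BH-adjusted.
* **Co-expression conservation (corCor)** — for each gene, the Pearson
  correlation between its two vectors of Spearman correlations with the
  other n−1 genes, computed in two matrices (two tissues, or the same
  tissue in two species); plus soft connectivity kᵢ = Σⱼ |rᵢⱼ|^β and its
  cross-species correlation over module gene sets.
* **Partitioning** — genes ranked by divergence score, cut into ten even
  windows (17,315 orthologs → 1731 per window, remainder dropped), and
  top/bottom 10% taken as diverged/conserved sets (orientation is
  metric-aware: high −log10 p is diverged, high corCor is conserved).
* **GWAS-signal enrichment** — T_sum = Σ b² over the markers within
  ±50 kb of a gene set, tested against a cyclical-permutation null that
  rotates the genome-ordered effect vector against the fixed mask;
  one-tailed empirical p. Hypergeometric overlap tests for gene sets.
* **Chromatin-state enrichment** — fold (C/A)/(B/D) of each state inside
  TSS ±2 kb windows of a gene set.

## Worked example

```python
import numpy as np, pandas as pd, orthoconserve as oc

# paired two-species matrices: 1000 orthologs, 4 tissues, 30 samples each,
# 10% of genes mean-shifted by 2 log2 units in species B
ea, eb, om, truth = oc.generate_paired_expression(
    n_genes=1000, n_tissues=4, samples_per_tissue=30, seed=42)

de = oc.differential_expression(
    ea.subset_tissue("tissue00"), eb.subset_tissue("tissue00"), om)
print("significant DE:", int(de.significant.sum()), "of", len(de))

scores = pd.Series(-np.log10(np.clip(de["p"], 1e-300, None)).to_numpy(),
                   index=de["gene_a"])
part = oc.conservation_partition(scores, metric="mean_expression_de")
recovered = len(set(part.diverged_set) & set(truth.diverged_gene_ids))
print("truth-diverged recovered:", recovered, "of", len(truth.diverged_gene_ids))

markers, ann, t2 = oc.generate_gwas_markers(
    n_markers=10_000, n_chroms=5, enriched_gene_set_size=50,
    enrichment_ratio=5.0, seed=42)
mask = oc.assign_markers(ann, markers, t2.enriched_gene_set, extension_bp=0)
res = oc.cyclical_permutation_test(markers.effects, mask, n_perm=10_000, seed=42)
print(f"T_sum = {res.t_sum_obs:.3f} over m_f = {res.m_f} markers; "
      f"null mean = {res.null_mean:.3f}; empirical p = {res.p_empirical:.2e}")
```

prints

```
significant DE: 108 of 1000
truth-diverged recovered: 100 of 100
T_sum = 26.917 over m_f = 500 markers; null mean = 6.023; empirical p = 1.00e-04
```

All 100 planted diverged genes land in the top-decile diverged set (the
8 extra DE flags are borderline false positives at the 1.2-fold
threshold), and the planted fivefold effect-variance inflation in the
50-gene set pushes T_sum far above its rotation null — the smallest p
reportable at 10,000 permutations with the +1 pseudo-count.

The same steps are available as shell commands (`orthoconserve simulate
/ summarize / de / diffvar / corcor / partition / snpmap / enrich /
statefold`); `orthoconserve --help` lists them.

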