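# Methods

## Scope and data model

The pipeline operates on paired bulk expression resources for two
species sharing a panel of one-to-one orthologs across common tissues.
Its raw substrate is a non-negative, dense gene × sample TPM matrix per
species with a tissue label per sample; downstream stages consume the
orthologs only, aligned through a bijective id map. All log-scale work
uses log2(TPM + 0.25); the 0.25 pseudo-count keeps zeros finite
(log2(0.25) = −2) and matches the scale on which the thresholds below
are defined. Genomic coordinates are 0-based half-open internally; the
annotation TSV is 1-based inclusive on disk (GFF-like) and converted on
load, BED segmentations are taken as-is, and marker positions stay
1-based until they meet an internal interval (converted with pos − 1).

## Conservation metrics

**Mean expression.** Per (gene, tissue): median TPM, mean and MAD of
log2(TPM+0.25), and CV = sd/mean of linear TPM (ddof = 1). The MAD is
deliberately unscaled (no 1.4826 consistency factor): only rankings and
correlations of MADs are consumed, so the scale cancels. A gene counts
as expressed in a tissue when its median TPM exceeds 0.1, strictly.
Between-species differential expression is a Welch two-sample t-test per
ortholog pair on log2(TPM+0.25) within a tissue; log2FC is the
difference of group means on that scale, and the significance flag
requires |log2FC| > log2(1.2) together with Benjamini–Hochberg
FDR < 0.05. Tissue-specific expression uses the same test one-vs-rest
with the stricter, direction-aware flag log2FC > 1.5 and FDR < 0.05.
An ordinary Welch t is used rather than a moderated (shrunken-variance)
t: the load-bearing content is the fold-change and FDR thresholds, and
with the sample sizes the pipeline targets (tens to hundreds per tissue)
variance moderation changes little. Degenerate rows — zero variance on
both sides — get p = 1 when means agree; when means differ, p is set to
the smallest positive float and flagged, which keeps every ranking total
instead of propagating NaNs.

**Variability.** f = s₁²/s₂² of log2(TPM+0.25) values, referred to
F(n−1, m−1). The test is two-sided (p doubles the smaller tail,
clipped at 1) since divergence in either direction is divergence; genes
are ranked downstream by −log10 FDR. s₂² = 0 with s₁² > 0 yields
f = ∞ with minimal p; both zero yields p = 1 with f flagged undefined.

**Co-expression (corCor).** For gene g in an n-gene matrix, vector A
holds the Spearman correlations (average ranks on ties) of g with the
other n−1 genes; vector A′ is built identically, in the same gene
order, in the second matrix; corCor(g) is the Pearson correlation of A
with A′. The Spearman inner layer makes the score invariant to any
per-gene monotone transform; self-correlations are excluded so the
vectors have length exactly n−1. Genes constant in either matrix are
removed from both backgrounds and flagged rather than zero-filled.
Soft connectivity is kᵢ = Σ_{j≠i} |Pearson rᵢⱼ|^β with β = 6 by default
(the common signed-network convention; configurable), and module wiring
conservation is the Pearson correlation of the two species'
connectivity vectors over a module's gene set.

## Partitioning and enrichment

Genes are ranked descending by the divergence score of each metric;
ties break lexicographically by gene id and undefined scores sink to
the bottom, so every ranking is a deterministic total order. Ten even
windows of size ⌊n/10⌋ are cut from the top; the n mod 10 lowest-ranked
genes are dropped (17,315 orthologs → 1731 per window). The top and
bottom 10% (⌊0.1·n⌋ each, computed from the full ranking, not from the
windows) form the diverged and conserved sets; orientation is
metric-dependent — for DE and variability the top of the ranking is
diverged, for corCor it is conserved — and is encoded once in the
partition layer rather than at call sites.

Markers are assigned to a gene set by extending gene bodies ±50 kb by
default (cis-regulatory flank); the flank boundary is inclusive after
coordinate conversion, windows of overlapping genes are merged so no
marker is double-counted, and the mask indexes the genome-ordered
marker table. The enrichment statistic is T_sum = Σ b² over masked
markers. Its null rotates the genome-ordered effect vector by an offset
drawn uniformly with replacement from 1..M−1 (offset 0 excluded),
holding the mask fixed — operationally equivalent to the genotype
cyclical permutation it emulates, while requiring no genotype matrix,
and preserving the local correlation structure of effects. The
one-tailed empirical p counts rotated statistics ≥ the observed one
(ties count against significance, the conservative reading) with a +1
pseudo-count in numerator and denominator so p is never zero; a
compatibility flag restores the pure proportion. A mask covering every
marker is rotation-invariant and short-circuits to p = 1 (avoiding
spurious sub-ulp comparisons of reordered sums).

Chromatin-state enrichment in TSS windows uses fold = (C/A)/(B/D): A
bases of the state genome-wide, B unique bases of the merged TSS ± 2 kb
windows of the gene set, C bases of their intersection, D the genome
size. The TSS is the annotated start for + strand genes and the last
base for − strand; a window spans the TSS base plus 2 kb on each side,
clamped to chromosome bounds. Because the segmentation tiles the genome
exactly once, Σ_states A = D and Σ_states C = B, which the tests assert.

Gene-set overlaps are tested with the upper-tail hypergeometric
P(X ≥ k) (the phyper(k−1, …, lower.tail = FALSE) convention).

## Synthetic data

The generator produces what the downstream stages need to be falsified:
paired matrices whose planted structure the pipeline must recover.
Defaults mirror the target study conditions — 17,315 orthologs, 20
shared tissues — with 50 samples per tissue as a desk-scale stand-in
for per-tissue cohorts in the hundreds; tests pass smaller sizes
explicitly and state them.

On the log2 scale each gene draws a baseline level ~ N(2.5, 2) and a
shared per-tissue deviation ~ N(0, 0.5), giving log-normal-like TPM
with tissue structure. Planted features, on mutually disjoint gene
subsets so each recovery test is unconfounded:

* diverged genes (10% by default) shift by ±2 log2 units in species B,
  sign random per gene (both species up- and down-regulate);
* variance-shifted genes multiply the species-B residual SD by √4;
* tissue-specific genes gain +4 log2 units in exactly one tissue;
* module genes (20 modules × 10 genes) add λ_g·f_m with per-sample
  standard-normal factors and loadings λ ~ Uniform(0.5, 1) with random
  sign — the minimal factor model that makes corCor discriminating;
  scrambled modules (half by default) redraw λ independently in
  species B, destroying the correlation pattern while keeping marginal
  variances comparable.

Residual noise is N(0, 1) on the log2 scale and
TPM = max(2^value − 0.25, 0). GWAS markers sit on a 1-kb lattice over
five chromosomes with gene bodies of 10 kb every 20 kb (so the default
10,000 markers give ~500 genes of 10 markers each); effects are
b ~ N(0, 0.1²), multiplied by √enrichment_ratio inside the planted
gene set. The segmentation tiles 200-bp windows with a uniform
15-state categorical, multiplying one state's odds by tss_bias inside
TSS ± 2 kb, covering every base exactly once. One global seed is split
into fixed per-generator substreams (expression = 0, markers = 1,
segmentation = 2) so adding a generator never shifts existing streams.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: library-size and batch effects, count
noise at low expression, realistic LD between markers, overlapping
truth categories, non-normal expression tails, and unbalanced sample
sizes between species. The recovery rates measured here are therefore
upper bounds on what identically-tuned thresholds achieve on real
resources.

## Numerical and design choices

* τ is computed on per-tissue median TPM without log transform (the
  index's conventional input); it is scale-invariant by construction.
* CV uses linear TPM with the n−1 sd estimator; undefined (mean 0)
  flagged rather than imputed.
* Hierarchical clustering of tissues uses 1 − Pearson distance with
  complete linkage; rows are sorted by label before linkage so ties
  resolve deterministically.
* BH FDR delegates to the standard step-up implementation and is
  cross-checked against a literal step-up oracle in the tests.
* Rotation offsets are sampled with replacement; exhaustive offset
  lists can be supplied for small-M exact nulls.
* The permutation gather is chunked to bound memory at large mask ×
  permutation products.
* Problem sizes in tests and the acceptance script (10,000 null genes
  for F calibration; 500 gene sets × 500 permutations for null
  uniformity; 100 seeds × 1,000 permutations for power; 1,000 genes ×
  50 samples for recovery; ~10,000 tiling windows for chromatin folds)
  are the package's chosen desk-scale study conditions, sized to make
  Monte-Carlo error small relative to each check's tolerance.

## Known limitations

Variance moderation (limma-style) is intentionally absent; at small
per-tissue n the Welch test loses power relative to it. The F-test
inherits its normality sensitivity — no robust (Levene/Brown–Forsythe)
variant is provided. Module *detection* is out of scope: modules enter
as gene sets (generator truth or user files). The cyclical permutation
operates on effect vectors, not genotypes, so it cannot model
mask-correlated LD beyond what genome ordering preserves. corCor is
O(n²) in genes and dense; very large backgrounds (≫10⁴ genes) need
blocking or subsetting by expressed genes, which is the default
background recommendation (genes expressed in the tissue in both
species).
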