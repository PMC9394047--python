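"""Paired two-species synthetic inputs with known ground truth.

The generators emulate the structure of a paired bulk-expression resource
for two species sharing a panel of one-to-one orthologs across common
tissues: log-normal-like TPM with shared tissue baselines, a designated
transcriptionally diverged subset (fixed log2 mean shift, random sign), a
variance-shifted subset, block co-expression induced by per-module latent
factors (scrambled modules redraw loadings in species B), tissue-specific
genes elevated in exactly one tissue, genome-ordered GWAS markers with
effect variance inflated inside a designated gene set, and a 200-bp-tiled
chromatin segmentation with one state biased towards TSS neighbourhoods.

Defaults mirror the study conditions the pipeline targets: 17,315
orthologs across 20 tissues; tests and examples pass smaller sizes
explicitly. One global seed is split into fixed per-generator substreams
(expression=0, markers=1, segmentation=2) so adding a generator never
shifts existing streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneAnnotation,
    MarkerTable,
    OrthologMap,
    ParameterError,
)

__all__ = [
    "SyntheticTruth",
    "generate_paired_expression",
    "generate_gwas_markers",
    "generate_segmentation",
]

_EXPRESSION_STREAM = 0
_MARKER_STREAM = 1
_SEGMENTATION_STREAM = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators (species-A gene ids)."""

    seed: int
    conserved_gene_ids: list = field(default_factory=list)
    diverged_gene_ids: list = field(default_factory=list)
    diverged_shift_sign: dict = field(default_factory=dict)
    variance_shifted_gene_ids: list = field(default_factory=list)
    variance_ratio_of_gene: dict = field(default_factory=dict)
    module_of_gene: dict = field(default_factory=dict)
    scrambled_coexpression_module_ids: list = field(default_factory=list)
    preserved_coexpression_module_ids: list = field(default_factory=list)
    tissue_specific_assignments: dict = field(default_factory=dict)
    enriched_gene_set: list = field(default_factory=list)
    tss_favored_state: str | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, default=str)


def generate_paired_expression(
    n_genes: int = 17_315,
    n_tissues: int = 20,
    samples_per_tissue: int = 50,
    frac_diverged: float = 0.10,
    mean_shift_log2: float = 2.0,
    frac_variance_shifted: float = 0.10,
    variance_ratio: float = 4.0,
    n_modules: int = 20,
    genes_per_module: int = 10,
    frac_modules_scrambled: float = 0.5,
    frac_tissue_specific: float = 0.05,
    tissue_specific_shift_log2: float = 4.0,
    noise_sd_log2: float = 1.0,
    seed: int = 0,
    species_a: str = "human",
    species_b: str = "cattle",
):
    """Generate paired expression matrices with planted structure.

    Returns ``(expr_a, expr_b, ortholog_map, truth)``. On the log2 scale,
    each gene gets a baseline shared between species (gene level ~
    N(2.5, 2), tissue deviation ~ N(0, 0.5)); diverged genes add a fixed
    +/- ``mean_shift_log2`` in species B; tissue-specific genes add
    ``tissue_specific_shift_log2`` in exactly one tissue (both species);
    module genes add loading * factor with per-sample standard-normal
    factors, loadings ~ Uniform(0.5, 1) with random sign, redrawn
    independently in species B for scrambled modules; residual noise is
    N(0, noise_sd_log2^2), with the residual SD multiplied by
    sqrt(variance_ratio) in species B for variance-shifted genes.
    TPM = max(2^value - 0.25, 0). The diverged, variance-shifted,
    tissue-specific and module gene subsets are mutually disjoint.
    """
    for name, frac in [
        ("frac_diverged", frac_diverged),
        ("frac_variance_shifted", frac_variance_shifted),
        ("frac_modules_scrambled", frac_modules_scrambled),
        ("frac_tissue_specific", frac_tissue_specific),
    ]:
        if not 0 <= frac <= 1:
            raise ParameterError(f"{name} must lie in [0, 1]")
    if n_genes < 10 * n_modules:
        raise ParameterError("need n_genes >= 10 * n_modules")
    if samples_per_tissue < 2 or n_tissues < 1:
        raise ParameterError("need >= 2 samples per tissue and >= 1 tissue")
    n_div = int(round(frac_diverged * n_genes))
    n_var = int(round(frac_variance_shifted * n_genes))
    n_ts = int(round(frac_tissue_specific * n_genes))
    n_mod_genes = n_modules * genes_per_module
    if n_div + n_var + n_ts + n_mod_genes > n_genes:
        raise ParameterError(
            "disjoint truth sets (diverged + variance-shifted + tissue-specific "
            "+ module genes) exceed n_genes"
        )

    rng = _rng(seed, _EXPRESSION_STREAM)
    width = max(5, len(str(n_genes)))
    genes_a = [f"A{i:0{width}d}" for i in range(n_genes)]
    genes_b = [f"B{i:0{width}d}" for i in range(n_genes)]
    tissues = [f"tissue{j:02d}" for j in range(n_tissues)]
    n_samples = n_tissues * samples_per_tissue

    perm = rng.permutation(n_genes)
    div_idx = perm[:n_div]
    var_idx = perm[n_div : n_div + n_var]
    ts_idx = perm[n_div + n_var : n_div + n_var + n_ts]
    mod_idx = perm[n_div + n_var + n_ts : n_div + n_var + n_ts + n_mod_genes]
    module_of = {}  # gene row -> module index
    for m in range(n_modules):
        for g in mod_idx[m * genes_per_module : (m + 1) * genes_per_module]:
            module_of[int(g)] = m
    n_scrambled = int(round(frac_modules_scrambled * n_modules))
    scrambled = set(rng.permutation(n_modules)[:n_scrambled].tolist())

    base_gene = rng.normal(2.5, 2.0, size=n_genes)
    tissue_dev = rng.normal(0.0, 0.5, size=(n_genes, n_tissues))
    signs = rng.choice([-1.0, 1.0], size=n_div)
    ts_tissue = rng.integers(0, n_tissues, size=n_ts)

    # shared structural mean per (gene, tissue)
    mean_log2 = base_gene[:, None] + tissue_dev
    mean_log2_b = mean_log2.copy()
    mean_log2_b[div_idx] += signs[:, None] * mean_shift_log2
    for g, t in zip(ts_idx, ts_tissue):
        mean_log2[g, t] += tissue_specific_shift_log2
        mean_log2_b[g, t] += tissue_specific_shift_log2

    lam_a = np.zeros(n_genes)
    lam_b = np.zeros(n_genes)
    if module_of:
        rows = np.fromiter(module_of.keys(), dtype=int)
        loadings = rng.uniform(0.5, 1.0, size=len(rows)) * rng.choice([-1.0, 1.0], size=len(rows))
        lam_a[rows] = loadings
        redraw = rng.uniform(0.5, 1.0, size=len(rows)) * rng.choice([-1.0, 1.0], size=len(rows))
        is_scr = np.array([module_of[int(r)] in scrambled for r in rows])
        lam_b[rows] = np.where(is_scr, redraw, loadings)

    sd_a = np.full(n_genes, noise_sd_log2)
    sd_b = sd_a.copy()
    sd_b[var_idx] *= np.sqrt(variance_ratio)

    def build(species, mean_gt, lam, sd, gene_ids):
        values = np.empty((n_genes, n_samples))
        sample_ids, tissue_labels = [], []
        col = 0
        for t, tissue in enumerate(tissues):
            factors = rng.standard_normal((n_modules, samples_per_tissue)) if n_modules else None
            eps = rng.standard_normal((n_genes, samples_per_tissue)) * sd[:, None]
            block = mean_gt[:, t][:, None] + eps
            if module_of:
                fac_rows = np.zeros((n_genes, samples_per_tissue))
                for g, m in module_of.items():
                    fac_rows[g] = lam[g] * factors[m]
                block += fac_rows
            values[:, col : col + samples_per_tissue] = block
            for k in range(samples_per_tissue):
                sample_ids.append(f"{species}_{tissue}_s{k:03d}")
                tissue_labels.append(tissue)
            col += samples_per_tissue
        tpm = np.maximum(np.exp2(values) - 0.25, 0.0)
        return ExpressionMatrix(
            species=species,
            values=pd.DataFrame(tpm, index=gene_ids, columns=sample_ids),
            tissue_of_sample=pd.Series(tissue_labels, index=sample_ids),
        )

    expr_a = build(species_a, mean_log2, lam_a, sd_a, genes_a)
    expr_b = build(species_b, mean_log2_b, lam_b, sd_b, genes_b)
    orthologs = OrthologMap(pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b}))

    truth_sets = set(div_idx) | set(var_idx)
    truth = SyntheticTruth(
        seed=seed,
        conserved_gene_ids=[genes_a[i] for i in range(n_genes) if i not in truth_sets],
        diverged_gene_ids=[genes_a[i] for i in sorted(div_idx)],
        diverged_shift_sign={genes_a[i]: float(s) for i, s in zip(div_idx, signs)},
        variance_shifted_gene_ids=[genes_a[i] for i in sorted(var_idx)],
        variance_ratio_of_gene={genes_a[i]: float(variance_ratio) for i in var_idx},
        module_of_gene={genes_a[g]: int(m) for g, m in sorted(module_of.items())},
        scrambled_coexpression_module_ids=sorted(scrambled),
        preserved_coexpression_module_ids=[m for m in range(n_modules) if m not in scrambled],
        tissue_specific_assignments={genes_a[g]: tissues[t] for g, t in zip(ts_idx, ts_tissue)},
        params={
            "n_genes": n_genes,
            "n_tissues": n_tissues,
            "samples_per_tissue": samples_per_tissue,
            "frac_diverged": frac_diverged,
            "mean_shift_log2": mean_shift_log2,
            "frac_variance_shifted": frac_variance_shifted,
            "variance_ratio": variance_ratio,
            "n_modules": n_modules,
            "genes_per_module": genes_per_module,
            "frac_modules_scrambled": frac_modules_scrambled,
            "frac_tissue_specific": frac_tissue_specific,
            "tissue_specific_shift_log2": tissue_specific_shift_log2,
            "noise_sd_log2": noise_sd_log2,
        },
    )
    return expr_a, expr_b, orthologs, truth


def generate_gwas_markers(
    n_markers: int = 10_000,
    n_chroms: int = 5,
    gene_annotation_spacing: int = 20_000,
    gene_length: int = 10_000,
    marker_spacing: int = 1_000,
    enriched_gene_set_size: int = 50,
    background_effect_sd: float = 0.1,
    enrichment_ratio: float = 1.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
):
    """Genome-ordered marker effects with a planted enriched gene set.

    Markers sit every ``marker_spacing`` bp; genes start every
    ``gene_annotation_spacing`` bp with bodies of ``gene_length`` bp laid
    evenly along ``n_chroms`` chromosomes (defaults: 10 markers per gene
    body, genes covering half the genome). Effects are b ~ N(0,
    background_effect_sd^2), multiplied by sqrt(enrichment_ratio) for
    markers inside genes of the enriched set. Returns
    ``(markers, annotation, truth)``.
    """
    if enrichment_ratio < 1:
        raise ParameterError("enrichment_ratio must be >= 1")
    if gene_length >= gene_annotation_spacing:
        raise ParameterError("gene_length must be < gene_annotation_spacing")
    per_chrom = n_markers // n_chroms
    if per_chrom < 1:
        raise ParameterError("need at least one marker per chromosome")
    rng = _rng(seed, _MARKER_STREAM)

    chrom_len = (per_chrom + 1) * marker_spacing
    genes_per_chrom = max((chrom_len - gene_annotation_spacing) // gene_annotation_spacing, 0)
    n_genes = genes_per_chrom * n_chroms
    if n_genes < 1:
        raise ParameterError("no room for genes; increase n_markers or shrink spacing")
    if n_markers < n_genes:
        raise ParameterError("n_markers must be >= number of genes")
    if enriched_gene_set_size > n_genes:
        raise ParameterError("enriched set larger than gene count")

    chroms = [f"chr{c + 1}" for c in range(n_chroms)]
    genome_sizes = {c: chrom_len for c in chroms}
    counts = [per_chrom] * n_chroms
    counts[-1] += n_markers - per_chrom * n_chroms

    m_rows, g_rows = [], []
    gid = 0
    width = max(5, len(str(n_genes)))
    for c, chrom in enumerate(chroms):
        for i in range(counts[c]):
            pos = (i + 1) * marker_spacing  # 1-based
            m_rows.append((f"m{len(m_rows):06d}", chrom, pos, 0.0))
        for j in range(genes_per_chrom):
            start1 = (j + 1) * gene_annotation_spacing + 1  # 1-based inclusive
            end1 = start1 + gene_length - 1
            strand = "+" if (gid % 2 == 0) else "-"
            g_rows.append((f"G{gid:0{width}d}", chrom, start1 - 1, end1, strand))
            gid += 1

    markers = pd.DataFrame(m_rows, columns=["marker", "chrom", "pos", "b"])
    annotation = GeneAnnotation(
        pd.DataFrame(g_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )

    markers["b"] = rng.normal(0.0, background_effect_sd, size=len(markers))
    enriched = sorted(
        annotation.table["gene_id"].iloc[
            rng.permutation(n_genes)[:enriched_gene_set_size]
        ].tolist()
    )
    ann = annotation.indexed().loc[enriched]
    inside = np.zeros(len(markers), dtype=bool)
    for chrom, grp in ann.groupby("chrom", sort=False):
        on = (markers["chrom"] == chrom).to_numpy()
        pos0 = markers.loc[on, "pos"].to_numpy() - 1
        hit = np.zeros(pos0.shape, dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            hit |= (pos0 >= s) & (pos0 < e)
        inside[np.flatnonzero(on)] = hit
    markers.loc[inside, "b"] *= np.sqrt(enrichment_ratio)

    table = MarkerTable(markers, chrom_order=chroms)
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    truth.enriched_gene_set = enriched
    truth.params.update(
        {
            "n_markers": n_markers,
            "n_chroms": n_chroms,
            "gene_annotation_spacing": gene_annotation_spacing,
            "gene_length": gene_length,
            "marker_spacing": marker_spacing,
            "enriched_gene_set_size": enriched_gene_set_size,
            "background_effect_sd": background_effect_sd,
            "enrichment_ratio": enrichment_ratio,
            "genome_sizes": genome_sizes,
        }
    )
    return table, annotation, truth


def generate_segmentation(
    gene_annotation: GeneAnnotation,
    genome_sizes: dict,
    state_near_tss: str = "state01",
    background_states=tuple(f"state{i:02d}" for i in range(2, 16)),
    tss_bias: float = 1.0,
    seed: int = 0,
    window_bp: int = 200,
    tss_window_bp: int = 2_000,
    truth: SyntheticTruth | None = None,
):
    """Chromatin segmentation tiled in 200-bp windows covering the genome.

    Every window draws a state from a uniform categorical over the 15
    states; for windows overlapping TSS +/- ``tss_window_bp`` of any
    annotated gene, the odds of ``state_near_tss`` are multiplied by
    ``tss_bias``. The tiling covers every base exactly once (the final
    partial window is kept). Returns ``(segmentation, truth)``.
    """
    from .io_formats import ChromatinSegmentation  # local to avoid cycle noise

    if tss_bias < 1:
        raise ParameterError("tss_bias must be >= 1")
    states = [state_near_tss, *background_states]
    if len(set(states)) != len(states):
        raise ParameterError("duplicate state labels")
    rng = _rng(seed, _SEGMENTATION_STREAM)

    ann = gene_annotation.table
    tss = ann["start"].where(ann["strand"] == "+", ann["end"] - 1)
    tss_by_chrom = {
        chrom: np.sort(tss[ann["chrom"] == chrom].to_numpy()) for chrom in set(ann["chrom"])
    }

    base_w = np.ones(len(states))
    tss_w = base_w.copy()
    tss_w[0] *= tss_bias
    rows = []
    for chrom, length in genome_sizes.items():
        starts = np.arange(0, length, window_bp)
        ends = np.minimum(starts + window_bp, length)
        near = np.zeros(len(starts), dtype=bool)
        sites = tss_by_chrom.get(chrom)
        if sites is not None and len(sites):
            lo = np.maximum(sites - tss_window_bp, 0)
            hi = sites + tss_window_bp + 1
            # window [s, e) overlaps some [lo_i, hi_i) iff more intervals
            # start before e than end at or before s (both arrays sorted)
            a = np.searchsorted(hi, starts, side="right")
            b = np.searchsorted(lo, ends, side="left")
            near = b > a
        for is_near in (False, True):
            sel = near == is_near
            if not sel.any():
                continue
            w = tss_w if is_near else base_w
            choice = rng.choice(len(states), size=int(sel.sum()), p=w / w.sum())
            for s, e, c in zip(starts[sel], ends[sel], choice):
                rows.append((chrom, int(s), int(e), states[c]))
    seg = ChromatinSegmentation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]), dict(genome_sizes)
    )
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    truth.tss_favored_state = state_near_tss
    truth.params.update(
        {"tss_bias": tss_bias, "segmentation_window_bp": window_bp, "tss_window_bp": tss_window_bp}
    )
    return seg, truth
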