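"""On-disk formats and validated in-memory containers.

Every table the pipeline touches is plain TSV except the chromatin
segmentation, which is BED4 accompanied by a two-column genome-sizes file.
Coordinate conventions:

* gene annotation TSV is 1-based inclusive on disk (GFF-like) and converted
  to 0-based half-open on load;
* BED segmentations are already 0-based half-open;
* marker positions stay 1-based as loaded (GWAS convention); consumers that
  intersect them with internal intervals convert with ``pos - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrthoconserveError",
    "FormatError",
    "ValidationError",
    "KeyingError",
    "ParameterError",
    "ExpressionMatrix",
    "OrthologMap",
    "GeneAnnotation",
    "MarkerTable",
    "ChromatinSegmentation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_marker_table",
    "write_marker_table",
    "read_genome_sizes",
    "write_genome_sizes",
    "read_segmentation",
    "write_segmentation",
    "read_gene_set",
    "write_gene_set",
]


class OrthoconserveError(ValueError):
    """Base class for all errors raised by this package."""


class FormatError(OrthoconserveError):
    """A file does not conform to its expected layout."""


class ValidationError(OrthoconserveError):
    """Values violate a container invariant."""


class KeyingError(OrthoconserveError):
    """An identifier fails to resolve (unknown sample, tissue, gene...)."""


class ParameterError(OrthoconserveError):
    """A caller-supplied parameter is out of its admissible range."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix for one species, with per-sample tissue labels.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``tissue_of_sample`` maps every sample id to a tissue label.
    """

    species: str
    values: pd.DataFrame
    tissue_of_sample: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite (no missing cells)")
        if (arr < 0).any():
            raise ValidationError("negative TPM values are not allowed")
        missing = v.columns.difference(self.tissue_of_sample.index)
        if len(missing):
            raise KeyingError(f"samples without a tissue label: {missing.tolist()[:5]}")
        self.tissue_of_sample = self.tissue_of_sample.reindex(v.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list[str]:
        return sorted(self.tissue_of_sample.unique())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        """Restrict to the samples of one tissue."""
        mask = self.tissue_of_sample == tissue
        if not mask.any():
            raise KeyingError(f"unknown tissue {tissue!r} for species {self.species!r}")
        cols = self.sample_ids[mask.to_numpy()]
        return ExpressionMatrix(
            self.species, self.values[cols], self.tissue_of_sample[cols]
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to (and order by) the given gene ids."""
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.gene_ids)
        if len(missing):
            raise KeyingError(f"unknown gene ids: {missing.tolist()[:5]}")
        return ExpressionMatrix(
            self.species, self.values.loc[gene_ids], self.tissue_of_sample
        )


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between species A and B (bijective)."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        p = self.pairs
        if list(p.columns) != ["gene_a", "gene_b"]:
            p = p.copy()
            p.columns = ["gene_a", "gene_b"]
            self.pairs = p
        if (p["gene_a"].astype(str).str.len() == 0).any() or (
            p["gene_b"].astype(str).str.len() == 0
        ).any():
            raise ValidationError("empty gene id in ortholog map")
        for side in ("gene_a", "gene_b"):
            if p[side].duplicated().any():
                dup = p.loc[p[side].duplicated(), side].tolist()
                raise ValidationError(
                    f"ortholog map not bijective; repeated on {side}: {dup[:5]}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> pd.Index:
        return pd.Index(self.pairs["gene_a"])

    @property
    def b_ids(self) -> pd.Index:
        return pd.Index(self.pairs["gene_b"])

    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))


@dataclass
class GeneAnnotation:
    """Gene locations; internally 0-based half-open.

    ``table`` columns: gene_id, chrom, start, end, strand. ``start < end``
    and strand is "+" or "-".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "chrom", "start", "end", "strand"]
        if not set(required).issubset(t.columns):
            raise FormatError(f"annotation requires columns {required}")
        t = t[required].reset_index(drop=True)
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene ids in annotation: {dup[:5]}")
        if not (t["start"] < t["end"]).all():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].tolist()
            raise ValidationError(f"start >= end for genes: {bad[:5]}")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")

    def tss(self) -> pd.Series:
        """0-based TSS position per gene: start for + strand, end-1 for -."""
        t = self.indexed()
        return t["start"].where(t["strand"] == "+", t["end"] - 1)


@dataclass
class MarkerTable:
    """Genome-ordered GWAS markers with per-marker effect sizes b.

    Genome order is load-bearing: the cyclical permutation null rotates the
    effect vector along this order. Chromosomes are ordered by their first
    appearance in ``chrom_order`` (the genome-sizes file when supplied,
    otherwise the input file itself); positions ascend within chromosome.
    """

    table: pd.DataFrame  # columns: marker, chrom, pos, b
    chrom_order: list = field(default_factory=list)
    input_was_sorted: bool = True

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker", "chrom", "pos", "b"]
        if not set(required).issubset(t.columns):
            raise FormatError(f"marker table requires columns {required}")
        t = t[required].reset_index(drop=True)
        if not np.isfinite(t["b"].to_numpy(dtype=float)).all():
            raise ValidationError("marker effects b must be finite")
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(t["chrom"]))
        unknown = set(t["chrom"]) - set(self.chrom_order)
        if unknown:
            raise KeyingError(f"marker chromosomes not in genome order: {sorted(unknown)[:5]}")
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        key = t["chrom"].map(rank)
        order = np.lexsort((t["pos"].to_numpy(), key.to_numpy()))
        self.input_was_sorted = bool((order == np.arange(len(t))).all())
        self.table = t.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def effects(self) -> np.ndarray:
        return self.table["b"].to_numpy(dtype=float)


@dataclass
class ChromatinSegmentation:
    """State-labelled genomic intervals (0-based half-open) plus genome sizes."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state
    genome_sizes: dict

    def __post_init__(self) -> None:
        t = self.intervals
        required = ["chrom", "start", "end", "state"]
        if not set(required).issubset(t.columns):
            raise FormatError(f"segmentation requires columns {required}")
        t = t[required].sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if not (t["start"] < t["end"]).all():
            raise ValidationError("segmentation intervals must have start < end")
        if (t["start"] < 0).any():
            raise ValidationError("negative interval start")
        unknown = set(t["chrom"]) - set(self.genome_sizes)
        if unknown:
            raise KeyingError(f"interval chromosomes missing from genome sizes: {sorted(unknown)[:5]}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if (grp["end"].to_numpy() > self.genome_sizes[chrom]).any():
                raise ValidationError(f"interval past end of chromosome {chrom}")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping intervals on chromosome {chrom}")
        self.intervals = t

    @property
    def states(self) -> list[str]:
        return sorted(self.intervals["state"].unique())

    def total_covered(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_expression_matrix(path, species: str, sample_sheet) -> ExpressionMatrix:
    """Load a TPM TSV (first column gene ids, header of sample ids) plus a
    two-column sample sheet (sample, tissue)."""
    df = _read_tsv(path, index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing expression cells are not allowed")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    sheet = _read_tsv(sample_sheet, header=0)
    if sheet.shape[1] < 2:
        raise FormatError(f"{sample_sheet}: expected columns sample, tissue")
    tissues = pd.Series(
        sheet.iloc[:, 1].astype(str).to_numpy(), index=sheet.iloc[:, 0].astype(str)
    )
    if tissues.index.duplicated().any():
        raise FormatError(f"{sample_sheet}: duplicate sample ids")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(species=species, values=df, tissue_of_sample=tissues)


def write_expression_matrix(em: ExpressionMatrix, path, sample_sheet) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample": em.sample_ids, "tissue": em.tissue_of_sample.to_numpy()}
    ).to_csv(sample_sheet, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    """Two-column TSV of paired gene ids; must be one-to-one."""
    df = _read_tsv(path, header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: ortholog map must have exactly two columns")
    df.columns = ["gene_a", "gene_b"]
    return OrthologMap(df)


def write_ortholog_map(om: OrthologMap, path) -> None:
    om.pairs.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    """Annotation TSV with 1-based inclusive coordinates; converted to
    0-based half-open on load (start-1, end unchanged)."""
    df = _read_tsv(path, header=0, dtype={"gene_id": str, "chrom": str})
    required = ["gene_id", "chrom", "start", "end", "strand"]
    if not set(required).issubset(df.columns):
        raise FormatError(f"{path}: annotation requires columns {required}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.table.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def read_marker_table(path, genome_sizes: dict | None = None) -> MarkerTable:
    """Marker TSV with columns marker, chrom, pos, b; rows are sorted to
    genome order if not already."""
    df = _read_tsv(path, header=0, dtype={"marker": str, "chrom": str})
    required = ["marker", "chrom", "pos", "b"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: marker table missing columns {sorted(missing)}")
    try:
        df["pos"] = df["pos"].astype(int)
        df["b"] = df["b"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric pos or b: {exc}") from exc
    order = list(genome_sizes) if genome_sizes else []
    return MarkerTable(df, chrom_order=order)


def write_marker_table(mt: MarkerTable, path) -> None:
    mt.table.to_csv(path, sep="\t", index=False)


def read_genome_sizes(path) -> dict:
    """Two-column chrom / length TSV; insertion order defines genome order."""
    df = _read_tsv(path, header=None, names=["chrom", "length"], dtype={0: str})
    if df["chrom"].duplicated().any():
        raise FormatError(f"{path}: duplicate chromosome")
    sizes = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    if any(v <= 0 for v in sizes.values()):
        raise ValidationError(f"{path}: non-positive chromosome length")
    return sizes


def write_genome_sizes(sizes: dict, path) -> None:
    pd.DataFrame(sizes.items()).to_csv(path, sep="\t", index=False, header=False)


def read_segmentation(bed_path, genome_sizes_path) -> ChromatinSegmentation:
    """BED4 chromatin segmentation (0-based half-open) plus genome sizes."""
    sizes = read_genome_sizes(genome_sizes_path)
    df = _read_tsv(
        bed_path, header=None, names=["chrom", "start", "end", "state"],
        dtype={0: str, 3: str},
    )
    if df["state"].isna().any():
        raise FormatError(f"{bed_path}: BED4 requires a state label in column 4")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return ChromatinSegmentation(df, sizes)


def write_segmentation(seg: ChromatinSegmentation, bed_path, genome_sizes_path) -> None:
    seg.intervals.to_csv(bed_path, sep="\t", index=False, header=False)
    write_genome_sizes(seg.genome_sizes, genome_sizes_path)


def read_gene_set(path) -> list[str]:
    """One gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(gene_ids, path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
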