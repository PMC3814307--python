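"""Readers and writers for the standard formats the pipeline touches.

Coordinates follow GFF3 conventions (1-based, inclusive) throughout the data
model; 0-based offsets appear only in motif hits, where they are documented
explicitly.  All readers validate strictly and raise :class:`FormatError`
rather than silently coercing malformed input, and every writer/reader pair
round-trips exactly on valid data.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneModel",
    "SampleTag",
    "CountMatrix",
    "parse_fasta",
    "write_fasta",
    "parse_gff3_gene_models",
    "write_gff3_gene_models",
    "read_count_matrix",
    "write_count_matrix",
    "read_profile_table",
    "write_profile_table",
    "read_annotation_map",
    "write_annotation_map",
    "write_target_table",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates, strand, translational start and exon structure.

    Parameters
    ----------
    gene_id
        Unique gene identifier.
    chrom
        Chromosome / contig name.
    strand
        ``"+"`` or ``"-"``.
    translational_start
        1-based genomic coordinate of the first base of the start codon
        (smallest CDS start on ``+``, largest CDS end on ``-``).  This is the
        exclusive anchor of the upstream promoter window.
    exon_intervals
        Sorted, non-overlapping 1-based inclusive ``(start, end)`` pairs.
        Their summed length is the modeled-exon length used as the
        denominator of the MRPKBME expression unit.
    """

    gene_id: str
    chrom: str
    strand: str
    translational_start: int
    exon_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exon_intervals:
            raise ValueError(f"gene {self.gene_id}: no exon intervals")
        prev_end = 0
        for start, end in self.exon_intervals:
            if start > end:
                raise ValueError(
                    f"gene {self.gene_id}: interval ({start}, {end}) reversed"
                )
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: intervals overlap or are unsorted"
                )
            prev_end = end

    @property
    def modeled_exon_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exon_intervals)


class SampleTag(NamedTuple):
    """Sample identity parsed from a ``strain_timepoint_rep`` column label."""

    strain: str
    timepoint: str
    replicate: str

    def __str__(self) -> str:  # round-trips with parse_sample_tag
        return f"{self.strain}_{self.timepoint}_{self.replicate}"


def parse_sample_tag(label: str) -> SampleTag:
    parts = label.split("_")
    if len(parts) != 3 or not all(parts):
        raise FormatError(
            f"sample label {label!r} does not follow the strain_timepoint_rep grammar"
        )
    return SampleTag(*parts)


@dataclass
class CountMatrix:
    """Non-negative integer counts, genes x samples.

    ``counts`` is an integer array of shape ``(len(gene_ids), len(samples))``.
    """

    gene_ids: list[str]
    samples: list[SampleTag]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in count matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample tags in count matrix")
        if (self.counts < 0).any():
            g, s = map(int, np.argwhere(self.counts < 0)[0])
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, sample {self.samples[s]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[str(s) for s in self.samples],
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: upper-cased sequence}``.

    The record id is the first whitespace-delimited token of the header.
    A sequence line before any header and duplicate ids are format errors.
    """
    path = Path(path)
    text = path.read_text()
    for line in text.splitlines():
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: sequence data before any FASTA header")
        break
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, one record per key, wrapped at ``width``."""
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            if not seq:
                handle.write("\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 0:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def parse_gff3_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Extract gene models from a GFF3 file.

    Per gene: strand comes from column 7; the translational start is the
    smallest CDS start on the ``+`` strand and the largest CDS end on ``-``;
    the modeled-exon length sums exon intervals, falling back to CDS
    intervals when no exon features are annotated.  CDS features without a
    gene ancestor and genes with strand ``"."`` are rejected.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        if not any(True for _ in db.parents(cds, featuretype="gene")):
            raise FormatError(f"CDS feature {cds.id!r} has no parent gene")

    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise FormatError(f"gene {gene.id!r} has strand {gene.strand!r}")
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        if not cds:
            raise FormatError(f"gene {gene.id!r} has no CDS features")
        if gene.strand == "+":
            translational_start = min(s for s, _ in cds)
        else:
            translational_start = max(e for _, e in cds)
        intervals = _merge_intervals(exons if exons else cds)
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            translational_start=translational_start,
            exon_intervals=intervals,
        )
    return models


def write_gff3_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for model in models.values():
            start = min(s for s, _ in model.exon_intervals)
            end = max(e for _, e in model.exon_intervals)
            handle.write(
                f"{model.chrom}\tqrepress\tgene\t{start}\t{end}\t.\t"
                f"{model.strand}\t.\tID={model.gene_id}\n"
            )
            for i, (s, e) in enumerate(model.exon_intervals):
                handle.write(
                    f"{model.chrom}\tqrepress\tCDS\t{s}\t{e}\t.\t"
                    f"{model.strand}\t0\tID={model.gene_id}.cds{i};Parent={model.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Count matrices and tables
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a tab-separated count table (first column ``gene_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    samples = [parse_sample_tag(c) for c in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                value = int(str(raw))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} for gene "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} for gene "
                    f"{df.index[i]!r}, sample {col!r}"
                )
            counts[i, j] = value
    return CountMatrix(list(df.index), samples, counts)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV, genes sorted lexicographically.

    Counts are zero-padded to a common width so that regenerated fixtures are
    byte-stable regardless of locale or formatting defaults.
    """
    order = np.argsort(matrix.gene_ids, kind="stable")
    width = max(1, len(str(int(matrix.counts.max(initial=0)))))
    with open(path, "w") as handle:
        handle.write("gene_id\t" + "\t".join(str(s) for s in matrix.samples) + "\n")
        for i in order:
            row = "\t".join(f"{int(c):0{width}d}" for c in matrix.counts[i])
            handle.write(f"{matrix.gene_ids[i]}\t{row}\n")


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x cycle-timepoint profile table (TSV, first col gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene id in profile table")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite value in profile table")
    return df.astype(float)


def write_profile_table(profiles: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\t" + "\t".join(map(str, profiles.columns)) + "\n")
        for gene, row in profiles.iterrows():
            handle.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read a flat two-column ``gene<TAB>category`` file into category->genes."""
    categories: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            gene, category = parts
            categories.setdefault(category, set()).add(gene)
    return categories


def write_annotation_map(categories: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for category in sorted(categories):
            for gene in sorted(categories[category]):
                handle.write(f"{gene}\t{category}\n")


def write_target_table(
    calls: Sequence,  # Sequence[TargetCall], kept untyped to avoid an import cycle
    timepoints: Sequence[str],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write per-gene target calls in the supplementary-table style.

    Columns: gene_id, gene_name, has_motif (TRUE/FALSE, site within the
    promoter window of the translational start), one log2(mutant/wild-type)
    ratio column per timepoint, and the direct/indirect/none class.
    """
    with open(path, "w") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        cols = ["gene_id", "gene_name", "has_motif"]
        cols += [f"log2_ratio_{tp}" for tp in timepoints]
        cols += ["class"]
        handle.write("\t".join(cols) + "\n")
        for call in calls:
            ratios = "\t".join(f"{call.log2_ratio[tp]:.4f}" for tp in timepoints)
            handle.write(
                f"{call.gene_id}\t{call.gene_name}\t"
                f"{'TRUE' if call.has_motif else 'FALSE'}\t{ratios}\t{call.cls}\n"
            )
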