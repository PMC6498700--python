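"""Shared data model: read layout, cells, genes, count matrix, experiment container.

All genomic coordinates are 0-based half-open internally.  Conversion to the
1-based conventions of GTF and genome-browser displays happens only at parse
time (:mod:`platepipe.features`) and in plot labels (:mod:`platepipe.qc`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ReadLayout",
    "CellRecord",
    "GeneModel",
    "CountMatrix",
    "ExperimentSet",
    "write_count_matrix",
    "read_count_matrix",
    "CountMatrixFormatError",
]

VALID_BASES = frozenset("ACGTN")


class CountMatrixFormatError(ValueError):
    """Raised when a count-matrix file violates the TSV dialect or invariants."""


@dataclass(frozen=True)
class ReadLayout:
    """Positional map of the cell barcode and UMI within read 1.

    Parameters
    ----------
    barcode_start, barcode_length
        0-based offset and length (bases) of the cell barcode in read 1.
    umi_start, umi_length
        0-based offset and length (bases) of the UMI in read 1.
    read2_keep
        If set, keep only this many leading bases of read 2 (3' trimming for
        low-quality tails); ``None`` keeps the full read.
    """

    barcode_start: int
    barcode_length: int
    umi_start: int
    umi_length: int
    read2_keep: Optional[int] = None

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.barcode_start < 0 or self.umi_start < 0:
            raise ValueError("layout offsets must be >= 0")
        if self.read2_keep is not None and self.read2_keep < 1:
            raise ValueError("read2_keep must be >= 1 when set")
        b = (self.barcode_start, self.barcode_start + self.barcode_length)
        u = (self.umi_start, self.umi_start + self.umi_length)
        if b[0] < u[1] and u[0] < b[1]:
            raise ValueError("barcode and UMI spans overlap")

    @property
    def min_read1_length(self) -> int:
        return max(
            self.barcode_start + self.barcode_length,
            self.umi_start + self.umi_length,
        )


@dataclass
class CellRecord:
    """One well/cell: identity, per-stage file paths, accumulating QC metrics."""

    cell_id: str
    experiment_id: str
    barcode: str
    fastq_path: Optional[Path] = None
    alignment_path: Optional[Path] = None
    metrics: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)


@dataclass
class GeneModel:
    """Per-gene exon-union intervals plus per-transcript exon structure.

    ``exon_union`` is the minimal sorted list of disjoint half-open intervals
    covering every exon of every transcript; it is the substrate for
    union-mode read assignment.
    """

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exon_union: List[Tuple[int, int]]
    transcripts: Dict[str, List[Tuple[int, int]]]
    is_spike_in: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        prev_end = None
        for start, end in self.exon_union:
            if start >= end:
                raise ValueError(f"empty exon-union interval in {self.gene_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"exon_union not sorted/disjoint in {self.gene_id}")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exon_union[0][0]

    @property
    def end(self) -> int:
        return self.exon_union[-1][1]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise CountMatrixFormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise CountMatrixFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise CountMatrixFormatError("counts must be integers")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise CountMatrixFormatError("counts must be non-negative")
        _check_unique(gene_ids, "gene")
        _check_unique(cell_ids, "cell")
        self.gene_ids: List[str] = list(gene_ids)
        self.cell_ids: List[str] = list(cell_ids)
        self.counts: np.ndarray = counts

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def column(self, cell_id: str) -> np.ndarray:
        return self.counts[:, self.cell_ids.index(cell_id)]

    def reorder_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CountMatrix(self.gene_ids, list(cell_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.gene_ids)} genes x {len(self.cell_ids)} cells)"


def write_count_matrix(matrix: CountMatrix, path: os.PathLike | str) -> Path:
    """Write ``matrix`` as UTF-8, tab-separated, Unix-newline text.

    First row is ``gene_id`` followed by the cell ids; one row per gene.
    Round-trips losslessly through :func:`read_count_matrix`.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.cell_ids) + "\n")
        for i, gid in enumerate(matrix.gene_ids):
            fh.write(gid + "\t" + "\t".join(map(str, matrix.counts[i])) + "\n")
    return path


def read_count_matrix(path: os.PathLike | str) -> CountMatrix:
    """Read a count matrix written by :func:`write_count_matrix`.

    Raises
    ------
    CountMatrixFormatError
        On ragged rows, non-integer or negative counts, or duplicate ids;
        the message names the offending line number (1-based).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise CountMatrixFormatError(f"{path}: empty file (line 1)")
        cols = header.rstrip("\n").split("\t")
        if cols[0] != "gene_id":
            raise CountMatrixFormatError(
                f"{path}: line 1: first column must be 'gene_id', got {cols[0]!r}"
            )
        cell_ids = cols[1:]
        gene_ids: List[str] = []
        rows: List[List[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise CountMatrixFormatError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                row = [int(v) for v in fields[1:]]
            except ValueError:
                raise CountMatrixFormatError(
                    f"{path}: line {lineno}: non-integer count"
                ) from None
            if any(v < 0 for v in row):
                raise CountMatrixFormatError(f"{path}: line {lineno}: negative count")
            rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(cell_ids)), dtype=np.int64)
    )
    try:
        return CountMatrix(gene_ids, cell_ids, counts)
    except CountMatrixFormatError as exc:
        raise CountMatrixFormatError(f"{path}: {exc}") from None


class ExperimentSet:
    """Container tying cells, gene summaries and the count matrix together.

    The stage functions (demultiplex, align, count) read and append to this
    container; when a matrix is present its ids must exactly match the cell
    and gene lists.
    """

    def __init__(
        self,
        cells: List[CellRecord],
        genes: List[GeneModel],
        matrix: Optional[CountMatrix] = None,
    ) -> None:
        cell_ids = [c.cell_id for c in cells]
        _check_unique(cell_ids, "cell")
        gene_ids = [g.gene_id for g in genes]
        _check_unique(gene_ids, "gene")
        if matrix is not None:
            if matrix.cell_ids != cell_ids or matrix.gene_ids != gene_ids:
                raise ValueError(
                    "matrix cell/gene ids do not match the annotation tables"
                )
        self.cells = cells
        self.genes = genes
        self.matrix = matrix

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row: Dict[str, object] = {
                "cell_id": c.cell_id,
                "experiment_id": c.experiment_id,
                "barcode": c.barcode,
                "fastq_path": str(c.fastq_path) if c.fastq_path else "",
                "alignment_path": str(c.alignment_path) if c.alignment_path else "",
                "flags": ";".join(c.flags),
            }
            row.update(c.metrics)
            rows.append(row)
        return pd.DataFrame(rows)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "gene_name": [g.gene_name for g in self.genes],
                "biotype": [g.biotype for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "is_spike_in": [g.is_spike_in for g in self.genes],
            }
        )

    def save(self, out_dir: os.PathLike | str) -> Path:
        """Serialize to a directory: cells.tsv, genes.tsv, counts.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cell_table().to_csv(out / "cells.tsv", sep="\t", index=False)
        self.gene_table().to_csv(out / "genes.tsv", sep="\t", index=False)
        if self.matrix is not None:
            write_count_matrix(self.matrix, out / "counts.tsv")
        return out
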