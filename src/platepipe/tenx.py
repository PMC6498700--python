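"""Per-cell alignment QC from Cell Ranger-style BAMs.

Restricts tallies to a filtered-barcode list: for each filtered barcode,
the number of primary mapped records carrying its (corrected) cell-barcode
tag, and the subset of those additionally carrying a gene-assignment tag.
Records from unfiltered barcodes are dropped, never reassigned.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Set

import pandas as pd
import pysam

__all__ = ["TenxCellQC", "read_filtered_barcodes", "tenx_bamqc", "tenx_qc_table"]


@dataclass(frozen=True)
class TenxCellQC:
    barcode: str
    reads_mapped: int
    reads_mapped_to_genes: int

    @property
    def fraction_gene_reads(self) -> float:
        return self.reads_mapped_to_genes / self.reads_mapped if self.reads_mapped else 0.0


def _normalize_barcode(bc: str) -> str:
    # Cell Ranger suffixes barcodes with a GEM-group marker like "-1"
    if "-" in bc:
        head, _, tail = bc.rpartition("-")
        if head and tail.isdigit():
            return head
    return bc


def read_filtered_barcodes(path: os.PathLike | str) -> List[str]:
    """One barcode per line; a trailing ``-1``-style suffix is stripped."""
    barcodes: List[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            bc = line.strip()
            if bc:
                barcodes.append(_normalize_barcode(bc))
    if not barcodes:
        raise ValueError(f"{path}: empty filtered-barcode list")
    return barcodes


def tenx_bamqc(
    bam_path: os.PathLike | str,
    filtered_barcodes: Sequence[str],
    run_label: str = "run",
) -> List[TenxCellQC]:
    """Per-filtered-barcode mapped-read and gene-read tallies from a BAM.

    The corrected cell barcode is read from the ``CB`` tag (``CR`` fallback
    with a warning); gene assignment is the presence of a ``GX`` tag
    (``GN`` fallback).  Only primary, mapped records count.  Barcodes from
    the list that never appear get zero rows; a BAM with no barcode tags at
    all is fatal.

    Output order follows the filtered-barcode list and is independent of
    BAM record order.
    """
    wanted: Set[str] = {_normalize_barcode(b) for b in filtered_barcodes}
    mapped: Dict[str, int] = {b: 0 for b in wanted}
    gene: Dict[str, int] = {b: 0 for b in wanted}
    saw_tag = False
    used_cr_fallback = False
    path = Path(bam_path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.has_tag("CB"):
                bc = rec.get_tag("CB")
            elif rec.has_tag("CR"):
                bc = rec.get_tag("CR")
                used_cr_fallback = True
            else:
                continue
            saw_tag = True
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            bc = _normalize_barcode(str(bc))
            if bc not in wanted:
                continue
            mapped[bc] += 1
            if rec.has_tag("GX") or rec.has_tag("GN"):
                gene[bc] += 1
    if not saw_tag:
        raise ValueError(
            f"{bam_path}: no CB/CR cell-barcode tags found; not a "
            "Cell Ranger-style alignment file"
        )
    if used_cr_fallback:
        warnings.warn(
            f"{bam_path}: fell back to raw CR barcode tags for some records",
            stacklevel=2,
        )
    seen_order: List[str] = []
    seen: Set[str] = set()
    for b in (_normalize_barcode(x) for x in filtered_barcodes):
        if b not in seen:
            seen.add(b)
            seen_order.append(b)
    return [
        TenxCellQC(
            barcode=b, reads_mapped=mapped[b], reads_mapped_to_genes=gene[b]
        )
        for b in seen_order
    ]


def tenx_qc_table(
    results: Dict[str, List[TenxCellQC]],
) -> pd.DataFrame:
    """Stack per-run QC rows (run_label -> rows) into one tidy table."""
    rows = []
    for label, cells in results.items():
        for c in cells:
            rows.append(
                {
                    "run_label": label,
                    "barcode": c.barcode,
                    "reads_mapped": c.reads_mapped,
                    "reads_mapped_to_genes": c.reads_mapped_to_genes,
                    "fraction_gene_reads": c.fraction_gene_reads,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "run_label",
            "barcode",
            "reads_mapped",
            "reads_mapped_to_genes",
            "fraction_gene_reads",
        ],
    )
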