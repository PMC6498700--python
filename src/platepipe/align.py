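"""Adapter around an external aligner (or pre-existing alignments).

No aligner is bundled: alignment is pluggable.  Either a shell command
template is run once per cell FASTQ, or ``assign_prealigned`` maps cells to
existing SAM/BAM files by filename stem.  Either way the adapter never
rewrites alignment records; it only records paths and mapped-read tallies,
and verifies that read names still carry the ``:UMI:`` tag downstream
counting depends on.
"""

from __future__ import annotations

import os
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import pysam

from .core import CellRecord
from .demux import parse_umi_tag

__all__ = [
    "AlignerSpec",
    "align_cells",
    "assign_prealigned",
    "tally_alignment",
    "UmiTagContractError",
]

_PLACEHOLDERS = ("{fastq}", "{out}", "{index}")


class UmiTagContractError(RuntimeError):
    """The aligner modified read names and dropped the UMI tag."""


@dataclass(frozen=True)
class AlignerSpec:
    """External aligner command contract.

    ``command_template`` must contain the ``{fastq}``, ``{out}`` and
    ``{index}`` placeholders; ``expected_output`` is ``sam`` or ``bam``.
    """

    command_template: str
    expected_output: str = "sam"

    def __post_init__(self) -> None:
        missing = [p for p in _PLACEHOLDERS if p not in self.command_template]
        if missing:
            raise ValueError(f"command template missing placeholders: {missing}")
        if self.expected_output not in ("sam", "bam"):
            raise ValueError("expected_output must be 'sam' or 'bam'")


def _open_alignment(path: Path) -> pysam.AlignmentFile:
    mode = "rb" if path.suffix == ".bam" else "r"
    return pysam.AlignmentFile(str(path), mode, check_sq=False)


def tally_alignment(path: os.PathLike | str, verify_umi: bool = True) -> dict:
    """Count primary records and primary mapped records in a SAM/BAM.

    A mapped read is a primary (non-secondary, non-supplementary) record
    with the unmapped flag clear.  With ``verify_umi`` every primary record
    name is checked for the ``:UMI:`` tag; a violation is fatal because the
    counting stage cannot recover the UMI.
    """
    total = 0
    mapped = 0
    with _open_alignment(Path(path)) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if verify_umi:
                try:
                    parse_umi_tag(rec.query_name)
                except ValueError:
                    raise UmiTagContractError(
                        f"{path}: read name {rec.query_name!r} lost its :UMI: "
                        "tag; the aligner must not modify read headers"
                    ) from None
            total += 1
            if not rec.is_unmapped:
                mapped += 1
    return {"total": total, "mapped": mapped}


def _record_tallies(cell: CellRecord, path: Path) -> None:
    tallies = tally_alignment(path)
    cell.alignment_path = path
    cell.metrics["reads_mapped"] = tallies["mapped"]
    denom = cell.metrics.get("reads_assigned", tallies["total"])
    cell.metrics["fraction_mapped"] = tallies["mapped"] / denom if denom else 0.0


def align_cells(
    cells: Sequence[CellRecord],
    spec: AlignerSpec,
    index_path: os.PathLike | str,
    out_dir: os.PathLike | str,
) -> List[CellRecord]:
    """Run the external aligner once per cell FASTQ.

    Each cell gains ``alignment_path`` plus ``reads_mapped`` and
    ``fraction_mapped`` metrics.  A nonzero exit or missing output is
    recorded as a per-cell failure (flag ``align_failed``) and the run
    continues; a stripped UMI tag is fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cell in cells:
        if cell.fastq_path is None:
            cell.flags.append("align_failed:no_fastq")
            continue
        out_path = out_dir / f"{cell.cell_id}.{spec.expected_output}"
        cmd = spec.command_template.format(
            fastq=str(cell.fastq_path), out=str(out_path), index=str(index_path)
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            cell.flags.append(f"align_failed:exit_{proc.returncode}")
            continue
        if not out_path.exists():
            cell.flags.append("align_failed:missing_output")
            continue
        _record_tallies(cell, out_path)
    return list(cells)


def assign_prealigned(
    cells: Sequence[CellRecord],
    aligned_dir: os.PathLike | str,
) -> List[CellRecord]:
    """Map cells to existing SAM/BAM files by filename stem (= cell_id).

    This is the test/bypass route: alignments produced outside the pipeline
    (any aligner that preserves read names) are adopted without rewriting.
    """
    aligned_dir = Path(aligned_dir)
    by_stem = {}
    for ext in ("*.sam", "*.bam"):
        for p in sorted(aligned_dir.glob(ext)):
            by_stem.setdefault(p.stem, p)
    for cell in cells:
        path = by_stem.get(cell.cell_id)
        if path is None:
            cell.flags.append("align_failed:missing_output")
            continue
        _record_tallies(cell, path)
    return list(cells)
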