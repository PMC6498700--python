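"""Union-mode gene assignment, UMI deduplication and per-cell metrics.

A read is assigned to a gene only when its aligned blocks overlap the exon
union of exactly one strand-compatible gene (featureCounts-style union
mode).  Per gene and cell, reads are collapsed to distinct UMIs; the count
matrix reports raw distinct-UMI counts, while a directional single-pass
collapse feeds the reads-per-corrected-UMI metrics only.
"""

from __future__ import annotations

import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .core import CellRecord, CountMatrix, ExperimentSet
from .demux import hamming, parse_umi_tag
from .features import GeneModelSet

__all__ = [
    "StrandMode",
    "ReadAssignment",
    "CellCountResult",
    "cigar_blocks",
    "assign_read_to_gene",
    "dedup_umis",
    "directional_clusters",
    "count_cell",
    "count_experiment",
    "UmiTagError",
    "ASSIGNED",
    "NO_FEATURE",
    "AMBIGUOUS",
    "UNMAPPED",
    "SECONDARY",
]

# assignment outcomes
ASSIGNED = "assigned"
NO_FEATURE = "no_feature"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"
SECONDARY = "secondary"

STRAND_MODES = ("sense", "antisense", "unstranded")

# CIGAR op codes: M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_REF_CONSUMING_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_BLOCK_SPLIT = 3  # N


class UmiTagError(ValueError):
    """An alignment record's read name lacks the ``:UMI:`` tag."""


@dataclass(frozen=True)
class StrandMode:
    """Strand compatibility policy for gene assignment."""

    mode: str = "sense"

    def __post_init__(self) -> None:
        if self.mode not in STRAND_MODES:
            raise ValueError(f"strand mode must be one of {STRAND_MODES}")

    def compatible(self, gene_strand: str, read_strand: str) -> bool:
        if self.mode == "unstranded":
            return True
        if self.mode == "sense":
            return gene_strand == read_strand
        return gene_strand != read_strand


@dataclass(frozen=True)
class ReadAssignment:
    outcome: str
    gene_id: Optional[str] = None
    umi: Optional[str] = None


def cigar_blocks(
    reference_start: int, cigartuples: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Reference blocks consumed by an alignment, split at introns.

    M/=/X/D consume reference within a block; N ends the current block and
    starts a new one; S/I/H/P consume no reference.
    """
    blocks: List[Tuple[int, int]] = []
    pos = reference_start
    block_start = None
    for op, length in cigartuples:
        if op in _REF_CONSUMING_IN_BLOCK:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _BLOCK_SPLIT:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        # S, I, H, P: no reference consumed
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def assign_read_to_gene(
    aligned_blocks: Sequence[Tuple[int, int]],
    chrom: str,
    read_strand: str,
    models: GeneModelSet,
    strand_mode: StrandMode = StrandMode("sense"),
) -> ReadAssignment:
    """Union-mode assignment: exactly one overlapping compatible gene.

    Candidate genes are those whose exon union overlaps ANY aligned block by
    at least one base and whose strand is compatible under ``strand_mode``.
    One candidate -> assigned; zero -> no_feature; two or more -> ambiguous.
    An unknown chromosome yields no_feature.
    """
    candidates: Dict[str, None] = {}
    for start, end in aligned_blocks:
        for gid, gstrand in models.lookup(chrom, start, end):
            if strand_mode.compatible(gstrand, read_strand):
                candidates[gid] = None
    if not candidates:
        return ReadAssignment(NO_FEATURE)
    if len(candidates) > 1:
        return ReadAssignment(AMBIGUOUS)
    return ReadAssignment(ASSIGNED, gene_id=next(iter(candidates)))


def dedup_umis(umis: Iterable[str]) -> Tuple[int, int]:
    """Collapse a UMI multiset to (raw_count, corrected_count).

    raw_count is the number of distinct strings; corrected_count is the
    number of clusters left by the directional single-pass collapse
    (:func:`directional_clusters`).  corrected_count <= raw_count.
    """
    counts = Counter(umis)
    if not counts:
        return 0, 0
    clusters = directional_clusters(counts)
    return len(counts), len(clusters)


def directional_clusters(counts: Dict[str, int]) -> Dict[str, List[str]]:
    """Directional single-pass UMI collapse.

    Distinct UMIs are visited in order of descending read support (ties
    broken lexicographically); a UMI is absorbed into an already-kept UMI
    when it lies within Hamming distance 1 of it and the kept UMI has at
    least twice its support.  Returns kept UMI -> absorbed members
    (including itself).
    """
    kept: Dict[str, List[str]] = {}
    for umi in sorted(counts, key=lambda u: (-counts[u], u)):
        absorbed = False
        for k in kept:
            if (
                len(k) == len(umi)
                and counts[k] >= 2 * counts[umi]
                and hamming(k, umi) == 1
            ):
                kept[k].append(umi)
                absorbed = True
                break
        if not absorbed:
            kept[umi] = [umi]
    return kept


_METRIC_NAMES = (
    "total_reads",
    "reads_mapped_to_genome",
    "reads_mapped_to_genes",
    "total_umis",
    "mito_umis",
    "protein_coding_umis",
    "genes_detected",
    "protein_coding_genes_detected",
    "reads_per_umi_median",
    "reads_per_umi_mean",
    "reads_per_corrected_umi_median",
    "reads_per_corrected_umi_mean",
    "genes_per_million_reads",
)


@dataclass
class CellCountResult:
    """Per-cell counting output: gene counts plus the QC metric set."""

    per_gene_umi_count: Dict[str, int] = field(default_factory=dict)
    per_gene_read_count: Dict[str, int] = field(default_factory=dict)
    metrics: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)


def _open_alignment(path: Path) -> pysam.AlignmentFile:
    mode = "rb" if path.suffix == ".bam" else "r"
    return pysam.AlignmentFile(str(path), mode, check_sq=False)


def count_cell(
    alignment_path: os.PathLike | str,
    models: GeneModelSet,
    strand_mode: StrandMode = StrandMode("sense"),
) -> CellCountResult:
    """Count one cell's alignment file into per-gene UMI counts and metrics.

    Every record must carry the ``:UMI:`` tag in its read name (fatal
    otherwise).  Secondary/supplementary records are skipped before
    assignment.  Spike-in genes are counted in the per-gene maps but
    excluded from the biological summary metrics.  Metrics with undefined
    denominators report 0 and set a quality flag.
    """
    alignment_path = Path(alignment_path)
    umis_per_gene: Dict[str, Counter] = defaultdict(Counter)
    n_total = 0
    n_mapped = 0
    n_assigned = 0

    with _open_alignment(alignment_path) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            try:
                _, umi = parse_umi_tag(rec.query_name)
            except ValueError as exc:
                raise UmiTagError(
                    f"{alignment_path}: record {rec.query_name!r} lacks a "
                    "valid :UMI: tag"
                ) from exc
            n_total += 1
            if rec.is_unmapped:
                continue
            n_mapped += 1
            blocks = cigar_blocks(rec.reference_start, rec.cigartuples or [])
            strand = "-" if rec.is_reverse else "+"
            assignment = assign_read_to_gene(
                blocks, rec.reference_name, strand, models, strand_mode
            )
            if assignment.outcome == ASSIGNED:
                n_assigned += 1
                umis_per_gene[assignment.gene_id][umi] += 1

    result = CellCountResult()
    reads_per_umi: List[int] = []  # per (gene, distinct UMI) read support
    reads_per_corrected: List[int] = []  # per (gene, directional cluster)
    for gid, counter in umis_per_gene.items():
        result.per_gene_umi_count[gid] = len(counter)
        result.per_gene_read_count[gid] = sum(counter.values())
        reads_per_umi.extend(counter.values())
        for members in directional_clusters(dict(counter)).values():
            reads_per_corrected.append(sum(counter[m] for m in members))

    bio_genes = [
        models.genes[g] for g in result.per_gene_umi_count
        if not models.genes[g].is_spike_in
    ]
    total_umis = sum(
        result.per_gene_umi_count[g.gene_id] for g in bio_genes
    )
    mito_umis = sum(
        result.per_gene_umi_count[g.gene_id] for g in bio_genes if models.is_mito(g)
    )
    pc_genes = [g for g in bio_genes if g.biotype == "protein_coding"]
    protein_coding_umis = sum(result.per_gene_umi_count[g.gene_id] for g in pc_genes)

    m = result.metrics
    m["total_reads"] = n_total
    m["reads_mapped_to_genome"] = n_mapped
    m["reads_mapped_to_genes"] = n_assigned
    m["total_umis"] = total_umis
    m["mito_umis"] = mito_umis
    m["protein_coding_umis"] = protein_coding_umis
    m["genes_detected"] = sum(
        1 for g in bio_genes if result.per_gene_umi_count[g.gene_id] > 0
    )
    m["protein_coding_genes_detected"] = sum(
        1 for g in pc_genes if result.per_gene_umi_count[g.gene_id] > 0
    )
    raw_umi_total = sum(result.per_gene_umi_count.values())
    corrected_total = len(reads_per_corrected)
    if raw_umi_total:
        m["reads_per_umi_mean"] = n_assigned / raw_umi_total
        m["reads_per_umi_median"] = float(median(reads_per_umi))
    else:
        m["reads_per_umi_mean"] = 0.0
        m["reads_per_umi_median"] = 0.0
        result.flags.append("no_umis")
    if corrected_total:
        m["reads_per_corrected_umi_mean"] = n_assigned / corrected_total
        m["reads_per_corrected_umi_median"] = float(median(reads_per_corrected))
    else:
        m["reads_per_corrected_umi_mean"] = 0.0
        m["reads_per_corrected_umi_median"] = 0.0
    if n_total:
        m["genes_per_million_reads"] = m["genes_detected"] / (n_total / 1_000_000)
    else:
        m["genes_per_million_reads"] = 0.0
        result.flags.append("no_reads")
    return result


def count_experiment(
    cells: Sequence[CellRecord],
    models: GeneModelSet,
    strand_mode: StrandMode = StrandMode("sense"),
) -> ExperimentSet:
    """Count every cell and assemble the gene x cell matrix.

    Matrix rows follow annotation (GTF encounter) order, columns follow the
    cell list.  A per-cell counting failure zeroes that column and flags the
    cell instead of aborting the run; the result is independent of cell
    processing order.
    """
    gene_ids = list(models.gene_order)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(gene_ids), len(cells)), dtype=np.int64)
    for j, cell in enumerate(cells):
        if cell.alignment_path is None:
            cell.flags.append("count_failed:no_alignment")
            _zero_metrics(cell)
            continue
        try:
            result = count_cell(cell.alignment_path, models, strand_mode)
        except (UmiTagError, OSError, ValueError) as exc:
            cell.flags.append(f"count_failed:{type(exc).__name__}")
            _zero_metrics(cell)
            continue
        for gid, n in result.per_gene_umi_count.items():
            counts[gene_pos[gid], j] = n
        cell.metrics.update(result.metrics)
        cell.flags.extend(result.flags)
    matrix = CountMatrix(gene_ids, [c.cell_id for c in cells], counts)
    return ExperimentSet(list(cells), [models.genes[g] for g in gene_ids], matrix)


def _zero_metrics(cell: CellRecord) -> None:
    for name in _METRIC_NAMES:
        cell.metrics.setdefault(name, 0.0)
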