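"""Synthetic desk-scale fixtures: reference, reads, alignments, and truth.

Generates a miniature genome (FASTA + GTF) with multi-exon genes on both
strands, a mitochondrial chromosome and spike-in contigs; a barcode
whitelist; a ground-truth molecule count matrix; paired FASTQ where read 1
encodes barcode+UMI and read 2 a 3'-biased transcript substring; and
per-cell SAM files.  Error and duplication processes are seeded and every
per-read fate is drawn once and recorded, so downstream assertions against
the :class:`TruthBundle` are exact, never statistical.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core import CountMatrix, GeneModel, ReadLayout, write_count_matrix
from .demux import DemuxStats, hamming, tag_header_with_umi
from .features import GeneModelSet, exon_union

__all__ = [
    "SimConfig",
    "ReadTruth",
    "TruthBundle",
    "simulate_reference",
    "simulate_truth_counts",
    "simulate_reads",
    "simulate_alignments",
    "simulate_all",
]

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# demultiplexing fates
FATE_CLEAN = "clean"
FATE_BC_ERROR = "bc_error"
FATE_UMI_ERROR = "umi_error"
FATE_LOW_QUALITY = "low_quality"

# alignment fates
ALN_ALIGNED = "aligned"
ALN_UNMAPPED = "unmapped"
ALN_INTRONIC = "intronic"
ALN_AMBIGUOUS = "ambiguous"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Knobs for the synthetic data generator.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 20
    n_cells: int = 12
    n_transcripts_per_gene: Tuple[int, int] = (1, 3)
    umi_length: int = 6
    barcode_length: int = 8
    read2_length: int = 50
    max_molecules_per_gene: int = 4
    duplication_factor: Tuple[int, int] = (3, 3)  # inclusive range of read copies
    barcode_error_rate: float = 0.0
    umi_error_rate: float = 0.0
    low_quality_rate: float = 0.0
    unmapped_rate: float = 0.0
    intronic_rate: float = 0.0
    ambiguous_rate: float = 0.0
    mito_gene_fraction: float = 0.1
    protein_coding_fraction: float = 0.8
    spike_in_genes: int = 2
    strand_mode: str = "sense"
    good_phred: int = 37
    bad_phred: int = 2
    phred_offset: int = 33
    demux_min_phred: int = 10
    demux_max_mismatch: int = 1
    experiment_id: str = "sim"

    def __post_init__(self) -> None:
        for name in (
            "barcode_error_rate",
            "umi_error_rate",
            "low_quality_rate",
            "unmapped_rate",
            "intronic_rate",
            "ambiguous_rate",
            "mito_gene_fraction",
            "protein_coding_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if isinstance(self.n_transcripts_per_gene, list):
            self.n_transcripts_per_gene = tuple(self.n_transcripts_per_gene)
        if isinstance(self.duplication_factor, int):
            self.duplication_factor = (self.duplication_factor, self.duplication_factor)
        elif isinstance(self.duplication_factor, list):
            self.duplication_factor = tuple(self.duplication_factor)

    @property
    def layout(self) -> ReadLayout:
        return ReadLayout(
            barcode_start=0,
            barcode_length=self.barcode_length,
            umi_start=self.barcode_length,
            umi_length=self.umi_length,
            read2_keep=None,
        )

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ReadTruth:
    """Ground truth for one read pair."""

    read_id: str
    cell_id: str
    barcode: str
    gene_id: str
    umi_true: str
    umi_observed: str
    demux_fate: str
    aln_fate: str = ALN_ALIGNED
    # private alignment payload (not serialized to the truth TSV)
    chrom: str = ""
    blocks: Tuple[Tuple[int, int], ...] = ()
    strand: str = "+"
    seq: str = ""


@dataclass
class TruthBundle:
    """Everything the tests need to verify the pipeline exactly."""

    counts: CountMatrix
    per_read_truth: Dict[str, ReadTruth]
    expected_demux_stats: DemuxStats
    whitelist: List[Tuple[str, str]]
    cell_ids: List[str]

    def counts_from_reads(self) -> CountMatrix:
        """Re-derive the molecule counts by aggregating per-read truth."""
        seen: Dict[Tuple[str, str], set] = {}
        for rt in self.per_read_truth.values():
            if rt.gene_id:
                seen.setdefault((rt.cell_id, rt.gene_id), set()).add(rt.umi_true)
        counts = np.zeros(self.counts.shape, dtype=np.int64)
        gpos = {g: i for i, g in enumerate(self.counts.gene_ids)}
        cpos = {c: j for j, c in enumerate(self.counts.cell_ids)}
        for (cid, gid), umis in seen.items():
            counts[gpos[gid], cpos[cid]] = len(umis)
        return CountMatrix(self.counts.gene_ids, self.counts.cell_ids, counts)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference simulation


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    gene_name: str,
    biotype: str,
    chrom: str,
    offset: int,
    n_tx_range: Tuple[int, int],
    is_spike: bool = False,
) -> Tuple[GeneModel, int]:
    """Build one multi-exon gene starting at ``offset``; returns it and the
    position just past the gene."""
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    n_exons = int(rng.integers(2, 5))
    pos = offset
    scaffold: List[Tuple[int, int]] = []
    for k in range(n_exons):
        # short exons are allowed so 3'-end reads sometimes span a junction
        exon_len = int(rng.integers(30, 201))
        scaffold.append((pos, pos + exon_len))
        pos += exon_len
        if k < n_exons - 1:
            pos += int(rng.integers(60, 151))  # intron
    n_tx = int(rng.integers(n_tx_range[0], n_tx_range[1] + 1))
    transcripts: Dict[str, List[Tuple[int, int]]] = {
        f"{gene_name}-201": list(scaffold)  # first transcript covers all exons
    }
    for t in range(1, n_tx):
        keep = sorted(
            rng.choice(n_exons, size=int(rng.integers(1, n_exons + 1)), replace=False)
        )
        transcripts[f"{gene_name}-2{t + 1:02d}"] = [scaffold[int(i)] for i in keep]
    model = GeneModel(
        gene_id=gene_id,
        gene_name=gene_name,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exon_union=exon_union(iv for ivs in transcripts.values() for iv in ivs),
        transcripts=transcripts,
        is_spike_in=is_spike,
    )
    return model, pos


def simulate_reference(
    config: SimConfig, out_dir: os.PathLike | str
) -> Tuple[Path, Path, GeneModelSet, Dict[str, str]]:
    """Write ref.fa and annotation.gtf; return their paths, the in-memory
    gene models, and the genome sequences keyed by chromosome."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    n_main = config.n_genes - n_mito
    if n_main < 1:
        raise ValueError("mito_gene_fraction leaves no genes on the main chromosome")

    order: List[str] = []
    genes: Dict[str, GeneModel] = {}
    chrom_cursor: Dict[str, int] = {"chr1": 200, "chrM": 200}
    for i in range(config.n_genes):
        chrom = "chrM" if i >= n_main else "chr1"
        gid = f"SIMG{i + 1:05d}"
        if chrom == "chrM":
            name = f"mt-Sim{i + 1}"
            biotype = "protein_coding"
        else:
            name = f"Sim{i + 1}"
            biotype = (
                "protein_coding"
                if rng.random() < config.protein_coding_fraction
                else "lincRNA"
            )
        model, end = _make_gene(
            rng, gid, name, biotype, chrom, chrom_cursor[chrom],
            config.n_transcripts_per_gene,
        )
        chrom_cursor[chrom] = end + int(rng.integers(150, 400))
        order.append(gid)
        genes[gid] = model
    for s in range(config.spike_in_genes):
        gid = f"ERCC-{s + 1:05d}"
        chrom = gid
        chrom_cursor[chrom] = 100
        model, end = _make_gene(
            rng, gid, gid, "spike_in", chrom, 100, (1, 1), is_spike=True
        )
        chrom_cursor[chrom] = end
        order.append(gid)
        genes[gid] = model

    models = GeneModelSet(genes=genes, gene_order=order)

    genome: Dict[str, str] = {}
    for chrom, cursor in chrom_cursor.items():
        genome[chrom] = _random_seq(rng, cursor + 200)

    fasta_path = out_dir / "ref.fa"
    with open(fasta_path, "w", newline="\n") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    gtf_path = out_dir / "annotation.gtf"
    with open(gtf_path, "w", newline="\n") as fh:
        for gid in order:
            g = genes[gid]
            for tx_name, exons in g.transcripts.items():
                for start, end in exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{tx_name}"; '
                        f'gene_name "{g.gene_name}"; gene_biotype "{g.biotype}"; '
                        f'transcript_name "{tx_name}";'
                    )
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{start + 1}\t{end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
    return fasta_path, gtf_path, models, genome


def make_whitelist(config: SimConfig, rng: np.random.Generator) -> List[Tuple[str, str]]:
    """Barcodes with pairwise Hamming distance >= 2*max_mismatch + 1, so a
    within-threshold observation is never ambiguous."""
    min_dist = 2 * config.demux_max_mismatch + 1
    barcodes: List[str] = []
    attempts = 0
    while len(barcodes) < config.n_cells:
        attempts += 1
        if attempts > 10_000 * config.n_cells:
            raise ValueError("cannot place enough well-separated barcodes")
        cand = _random_seq(rng, config.barcode_length)
        if all(hamming(cand, b) >= min_dist for b in barcodes):
            barcodes.append(cand)
    return [(b, f"well{i + 1:02d}") for i, b in enumerate(barcodes)]


def simulate_truth_counts(
    config: SimConfig, models: GeneModelSet, cell_ids: Sequence[str],
    rng: np.random.Generator,
) -> CountMatrix:
    """True molecules per gene per cell: uniform on [0, max_molecules]."""
    counts = rng.integers(
        0,
        config.max_molecules_per_gene + 1,
        size=(len(models.gene_order), len(cell_ids)),
    )
    return CountMatrix(list(models.gene_order), list(cell_ids), counts)


# ---------------------------------------------------------------------------
# Read simulation


def _transcript_seq(genome: Dict[str, str], gene: GeneModel, exons) -> str:
    plus = "".join(genome[gene.chrom][s:e] for s, e in exons)
    return revcomp(plus) if gene.strand == "-" else plus


def _map_transcript_interval(
    exons: Sequence[Tuple[int, int]], strand: str, t0: int, t1: int
) -> List[Tuple[int, int]]:
    """Map transcript-coordinate [t0, t1) (5'->3' of the mRNA) onto genomic
    blocks (ascending)."""
    total = sum(e - s for s, e in exons)
    if strand == "-":
        t0, t1 = total - t1, total - t0
    blocks: List[Tuple[int, int]] = []
    cursor = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(t0, cursor), min(t1, cursor + length)
        if lo < hi:
            blocks.append((s + lo - cursor, s + hi - cursor))
        cursor += length
    return blocks


def simulate_reads(
    config: SimConfig,
    models: GeneModelSet,
    truth_counts: CountMatrix,
    genome: Dict[str, str],
    out_dir: os.PathLike | str,
    whitelist: Optional[List[Tuple[str, str]]] = None,
) -> Tuple[Path, Path, TruthBundle]:
    """Emit paired FASTQ for every true molecule and record every fate.

    Each molecule gets a UMI distinct within its (cell, gene) and emits a
    seeded number of duplicate read pairs.  Per-read demultiplexing fates
    (clean / bc_error / umi_error / low_quality) are drawn once, applied to
    the sequences/qualities, and recorded; ``expected_demux_stats`` is then
    exact bookkeeping, not an expectation.
    """
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if whitelist is None:
        whitelist = make_whitelist(config, rng)
    barcodes = [b for b, _ in whitelist]
    cell_ids = [f"{config.experiment_id}_{b}" for b in barcodes]
    if truth_counts.cell_ids != cell_ids:
        truth_counts = CountMatrix(
            truth_counts.gene_ids, cell_ids, truth_counts.counts
        )

    layout = config.layout
    dup_lo, dup_hi = config.duplication_factor
    good_q = chr(config.good_phred + config.phred_offset)
    bad_q = chr(config.bad_phred + config.phred_offset)

    reads: List[ReadTruth] = []
    serial = 0
    gpos = {g: i for i, g in enumerate(truth_counts.gene_ids)}
    for j, (bc, _label) in enumerate(whitelist):
        cell_id = cell_ids[j]
        for gid in models.gene_order:
            gene = models.genes[gid]
            n_mol = int(truth_counts.counts[gpos[gid], j])
            used_umis: set = set()
            for _mol in range(n_mol):
                while True:
                    umi = _random_seq(rng, config.umi_length)
                    if umi not in used_umis:
                        used_umis.add(umi)
                        break
                tx_names = sorted(gene.transcripts)
                tx = tx_names[int(rng.integers(0, len(tx_names)))]
                exons = gene.transcripts[tx]
                tlen = sum(e - s for s, e in exons)
                rlen = min(config.read2_length, tlen)
                # 3'-biased: read ends within the last few bases of the mRNA
                slack = int(rng.integers(0, min(6, tlen - rlen + 1)))
                t1 = tlen - slack
                t0 = t1 - rlen
                blocks = _map_transcript_interval(exons, gene.strand, t0, t1)
                mrna = _transcript_seq(genome, gene, exons)
                read_seq = mrna[t0:t1]
                n_copies = int(rng.integers(dup_lo, dup_hi + 1))
                for _copy in range(n_copies):
                    serial += 1
                    reads.append(
                        ReadTruth(
                            read_id=f"SIM:{serial:07d}",
                            cell_id=cell_id,
                            barcode=bc,
                            gene_id=gid,
                            umi_true=umi,
                            umi_observed=umi,
                            demux_fate=FATE_CLEAN,
                            chrom=gene.chrom,
                            blocks=tuple(blocks),
                            strand=gene.strand,
                            seq=read_seq,
                        )
                    )

    # shuffle read order so per-cell files exercise interleaving
    perm = rng.permutation(len(reads))
    reads = [reads[int(i)] for i in perm]

    # draw demultiplexing fates once, record them
    for rt in reads:
        u = rng.random()
        if u < config.low_quality_rate:
            rt.demux_fate = FATE_LOW_QUALITY
        elif u < config.low_quality_rate + config.barcode_error_rate:
            rt.demux_fate = FATE_BC_ERROR
        elif (
            u
            < config.low_quality_rate
            + config.barcode_error_rate
            + config.umi_error_rate
        ):
            rt.demux_fate = FATE_UMI_ERROR
            pos = int(rng.integers(0, config.umi_length))
            rt.umi_observed = _mutate(rng, rt.umi_true, [pos])

    stats = DemuxStats(per_cell_assigned={b: 0 for b in barcodes})
    r1_path = out_dir / "r1.fastq.gz"
    r2_path = out_dir / "r2.fastq.gz"
    fh1 = gzip.GzipFile(
        filename="", mode="wb", fileobj=open(r1_path, "wb"), mtime=0
    )
    fh2 = gzip.GzipFile(
        filename="", mode="wb", fileobj=open(r2_path, "wb"), mtime=0
    )
    try:
        for rt in reads:
            stats.total_pairs += 1
            obs_bc = rt.barcode
            r1 = list(_random_seq(rng, layout.min_read1_length))
            q1 = [good_q] * layout.min_read1_length
            if rt.demux_fate == FATE_BC_ERROR:
                # force distance > max_mismatch from EVERY whitelist barcode
                k = config.demux_max_mismatch + 1
                while True:
                    positions = rng.choice(
                        config.barcode_length, size=k, replace=False
                    )
                    cand = _mutate(rng, rt.barcode, [int(p) for p in positions])
                    if all(
                        hamming(cand, b) > config.demux_max_mismatch
                        for b in barcodes
                    ):
                        obs_bc = cand
                        break
                stats.unmatched_pairs += 1
            elif rt.demux_fate == FATE_LOW_QUALITY:
                span = layout.min_read1_length
                q1[int(rng.integers(0, span))] = bad_q
                stats.low_quality_pairs += 1
            else:
                stats.assigned_pairs += 1
                stats.per_cell_assigned[rt.barcode] += 1
            bs = layout.barcode_start
            r1[bs : bs + layout.barcode_length] = obs_bc
            us = layout.umi_start
            r1[us : us + layout.umi_length] = rt.umi_observed
            fh1.write(
                f"@{rt.read_id}\n{''.join(r1)}\n+\n{''.join(q1)}\n".encode("ascii")
            )
            q2 = good_q * len(rt.seq)
            fh2.write(
                f"@{rt.read_id}\n{rt.seq}\n+\n{q2}\n".encode("ascii")
            )
    finally:
        for h in (fh1, fh2):
            fileobj = h.fileobj
            h.close()
            fileobj.close()
    stats.validate()

    bundle = TruthBundle(
        counts=truth_counts,
        per_read_truth={rt.read_id: rt for rt in reads},
        expected_demux_stats=stats,
        whitelist=list(whitelist),
        cell_ids=cell_ids,
    )
    return r1_path, r2_path, bundle


# ---------------------------------------------------------------------------
# Alignment simulation


def _sam_cigar(blocks: Sequence[Tuple[int, int]]) -> str:
    parts = []
    for k, (s, e) in enumerate(blocks):
        if k:
            parts.append(f"{s - blocks[k - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _pick_intron_site(
    models: GeneModelSet, read_len: int
) -> Optional[Tuple[str, int, int]]:
    for gene in models:
        for (s1, e1), (s2, _e2) in zip(gene.exon_union, gene.exon_union[1:]):
            if s2 - e1 >= read_len + 2:
                return gene.chrom, e1 + 1, e1 + 1 + read_len
    return None


def _pick_ambiguous_site(
    models: GeneModelSet, block_len: int = 20
) -> Optional[Tuple[str, Tuple[Tuple[int, int], Tuple[int, int]], str]]:
    by_key: Dict[Tuple[str, str], List[GeneModel]] = {}
    for gene in models:
        if gene.is_spike_in:
            continue
        by_key.setdefault((gene.chrom, gene.strand), []).append(gene)
    for (chrom, strand), gs in sorted(by_key.items()):
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            ea = a.exon_union[-1]
            eb = b.exon_union[0]
            if ea[1] - ea[0] >= block_len and eb[1] - eb[0] >= block_len:
                blk1 = (ea[1] - block_len, ea[1])
                blk2 = (eb[0], eb[0] + block_len)
                if blk1[1] < blk2[0]:
                    return chrom, (blk1, blk2), strand
    return None


def simulate_alignments(
    truth: TruthBundle,
    models: GeneModelSet,
    genome: Dict[str, str],
    config: SimConfig,
    out_dir: os.PathLike | str,
) -> Dict[str, Path]:
    """Write one SAM per cell for the demux-assigned reads.

    Clean reads become primary records at their true location with correct
    strand flag and CIGAR (spliced reads use N).  Per cell, exact counts of
    reads — round(rate x n) — are converted to unmapped, intronic, or
    ambiguous-locus records, and each conversion is recorded in the read's
    ``aln_fate`` so tallies are deterministic.
    """
    rng = np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_cell: Dict[str, List[ReadTruth]] = {c: [] for c in truth.cell_ids}
    for rt in truth.per_read_truth.values():
        if rt.demux_fate in (FATE_CLEAN, FATE_UMI_ERROR):
            per_cell[rt.cell_id].append(rt)
    for cell_id in per_cell:
        per_cell[cell_id].sort(key=lambda rt: rt.read_id)

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(genome):
        header_lines.append(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}")
    header = "\n".join(header_lines) + "\n"

    intron_site = _pick_intron_site(models, 30)
    ambig_site = _pick_ambiguous_site(models)
    paths: Dict[str, Path] = {}
    for cell_id, cell_reads in per_cell.items():
        n = len(cell_reads)
        k_unmapped = int(round(config.unmapped_rate * n))
        k_intronic = int(round(config.intronic_rate * n))
        k_ambig = int(round(config.ambiguous_rate * n))
        if k_intronic and intron_site is None:
            raise ValueError("no intron long enough for intronic records")
        if k_ambig and ambig_site is None:
            raise ValueError("no same-strand gene pair for ambiguous records")
        chosen = rng.choice(n, size=min(n, k_unmapped + k_intronic + k_ambig),
                            replace=False) if n else np.array([], dtype=int)
        for idx in chosen[:k_unmapped]:
            cell_reads[int(idx)].aln_fate = ALN_UNMAPPED
        for idx in chosen[k_unmapped : k_unmapped + k_intronic]:
            cell_reads[int(idx)].aln_fate = ALN_INTRONIC
        for idx in chosen[k_unmapped + k_intronic :]:
            cell_reads[int(idx)].aln_fate = ALN_AMBIGUOUS

        path = out_dir / f"{cell_id}.sam"
        with open(path, "w", newline="\n") as fh:
            fh.write(header)
            for rt in cell_reads:
                qname = tag_header_with_umi(rt.read_id, rt.umi_observed)
                if rt.aln_fate == ALN_UNMAPPED:
                    fh.write(
                        f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{rt.seq}\t"
                        f"{'I' * len(rt.seq)}\n"
                    )
                    continue
                if rt.aln_fate == ALN_INTRONIC:
                    chrom, s, e = intron_site  # type: ignore[misc]
                    blocks: Tuple[Tuple[int, int], ...] = ((s, e),)
                    strand = rt.strand
                    seq = genome[chrom][s:e]
                elif rt.aln_fate == ALN_AMBIGUOUS:
                    chrom, blocks, strand = ambig_site  # type: ignore[misc]
                    seq = "".join(genome[chrom][s:e] for s, e in blocks)
                else:
                    chrom, blocks, strand = rt.chrom, rt.blocks, rt.strand
                    seq = rt.seq if strand == "+" else revcomp(rt.seq)
                flag = 16 if strand == "-" else 0
                pos = blocks[0][0] + 1
                cigar = _sam_cigar(blocks)
                fh.write(
                    f"{qname}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                    f"{seq}\t{'I' * len(seq)}\n"
                )
        paths[cell_id] = path
    return paths


# ---------------------------------------------------------------------------
# Orchestration


def write_truth(truth: TruthBundle, out_dir: os.PathLike | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(truth.counts, out / "counts.tsv")
    with open(out / "per_read_truth.tsv", "w", newline="\n") as fh:
        fh.write(
            "read_id\tcell_id\tbarcode\tgene_id\tumi_true\tumi_observed\t"
            "demux_fate\taln_fate\n"
        )
        for rid in sorted(truth.per_read_truth):
            rt = truth.per_read_truth[rid]
            fh.write(
                f"{rt.read_id}\t{rt.cell_id}\t{rt.barcode}\t{rt.gene_id}\t"
                f"{rt.umi_true}\t{rt.umi_observed}\t{rt.demux_fate}\t"
                f"{rt.aln_fate}\n"
            )
    s = truth.expected_demux_stats
    with open(out / "expected_stats.tsv", "w", newline="\n") as fh:
        fh.write("category\tbarcode\tcount\n")
        for name in (
            "total_pairs",
            "assigned_pairs",
            "low_quality_pairs",
            "unmatched_pairs",
            "ambiguous_pairs",
        ):
            fh.write(f"{name}\t.\t{getattr(s, name)}\n")
        for bc, nn in s.per_cell_assigned.items():
            fh.write(f"per_cell_assigned\t{bc}\t{nn}\n")
    return out


def simulate_all(config: SimConfig, out_dir: os.PathLike | str) -> dict:
    """Full fixture bundle: reference, whitelist, reads, truth, SAMs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta, gtf, models, genome = simulate_reference(config, out_dir)
    rng = np.random.default_rng(config.seed + 3)
    whitelist = make_whitelist(config, rng)
    cell_ids = [f"{config.experiment_id}_{b}" for b, _ in whitelist]
    truth_counts = simulate_truth_counts(config, models, cell_ids, rng)
    r1, r2, truth = simulate_reads(
        config, models, truth_counts, genome, out_dir, whitelist=whitelist
    )
    wl_path = out_dir / "whitelist.tsv"
    with open(wl_path, "w", newline="\n") as fh:
        fh.write("barcode\twell_label\n")
        for bc, label in whitelist:
            fh.write(f"{bc}\t{label}\n")
    sam_paths = simulate_alignments(truth, models, genome, config, out_dir / "sam")
    write_truth(truth, out_dir / "truth")
    return {
        "fasta": fasta,
        "gtf": gtf,
        "models": models,
        "genome": genome,
        "whitelist": wl_path,
        "whitelist_entries": whitelist,
        "r1": r1,
        "r2": r2,
        "truth": truth,
        "sam_paths": sam_paths,
    }
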