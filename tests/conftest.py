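"""Shared fixtures: in-memory gene models, SAM writers, and simulated runs."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence, Tuple

import pytest

from platepipe.core import GeneModel
from platepipe.features import GeneModelSet
from platepipe.simulate import SimConfig, simulate_all


def make_models(genes: Sequence[GeneModel]) -> GeneModelSet:
    return GeneModelSet(
        genes={g.gene_id: g for g in genes},
        gene_order=[g.gene_id for g in genes],
    )


def simple_gene(
    gene_id: str,
    chrom: str = "chr1",
    strand: str = "+",
    exons: Sequence[Tuple[int, int]] = ((99, 300),),
    biotype: str = "protein_coding",
    is_spike_in: bool = False,
    gene_name: str | None = None,
) -> GeneModel:
    exons = [tuple(e) for e in exons]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exon_union=list(exons),
        transcripts={f"{gene_id}-201": list(exons)},
        is_spike_in=is_spike_in,
    )


def write_sam(
    path: Path,
    chrom_lengths: Dict[str, int],
    records: Sequence[Tuple[str, int, str, int, str, str]],
) -> Path:
    """records: (qname, flag, chrom, pos0, cigar, seq); unmapped uses chrom='*'."""
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, chrom, pos0, cigar, seq in records:
            if chrom == "*":
                fh.write(f"{qname}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
            else:
                fh.write(
                    f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t"
                    f"{seq}\t{'I' * len(seq)}\n"
                )
    return path


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory) -> dict:
    """Error-free desk-scale run: 20 genes x 12 cells, duplication 3."""
    out = tmp_path_factory.mktemp("clean_sim")
    config = SimConfig(seed=11)
    bundle = simulate_all(config, out)
    bundle["config"] = config
    bundle["out_dir"] = out
    return bundle


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory) -> dict:
    """Run with seeded barcode, quality and UMI errors plus alignment fates."""
    out = tmp_path_factory.mktemp("noisy_sim")
    config = SimConfig(
        seed=23,
        barcode_error_rate=0.1,
        umi_error_rate=0.05,
        low_quality_rate=0.08,
        unmapped_rate=0.1,
        intronic_rate=0.05,
        ambiguous_rate=0.05,
    )
    bundle = simulate_all(config, out)
    bundle["config"] = config
    bundle["out_dir"] = out
    return bundle
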