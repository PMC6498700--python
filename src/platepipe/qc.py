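"""QC boxplots and genomic track views (reads colored by UMI, isoform exons).

Plot-data builders are pure functions returning plain data structures; the
matplotlib renderers consume only builder output, so every figure's content
is testable without rendering.  Display coordinates are 1-based inclusive
(genome-browser convention); internals stay 0-based half-open.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pysam
from matplotlib.backends.backend_pdf import PdfPages

from .core import CellRecord
from .counting import cigar_blocks
from .demux import parse_umi_tag
from .features import GeneModelSet

__all__ = [
    "ReadTrackDatum",
    "IsoformTrackDatum",
    "QC_METRIC_COLUMNS",
    "build_qc_table",
    "qc_plot_data",
    "qc_plots",
    "rview_data",
    "gview_data",
    "combine_tracks",
    "umi_color",
]

# Metric columns of the per-cell QC table, in report order.
QC_METRIC_COLUMNS = (
    "total_reads",
    "reads_mapped_to_genome",
    "reads_mapped_to_genes",
    "fraction_mapped_to_genome",
    "fraction_gene_reads_of_mapped",
    "fraction_gene_reads_of_total",
    "total_umis",
    "mito_umis",
    "fraction_mito_umis",
    "genes_detected",
    "fraction_protein_coding_genes",
    "fraction_protein_coding_umis",
    "reads_per_umi_median",
    "reads_per_umi_mean",
    "reads_per_corrected_umi_median",
    "reads_per_corrected_umi_mean",
    "genes_per_million_reads",
)


@dataclass(frozen=True)
class ReadTrackDatum:
    """One read arrow: genomic span, strand, UMI, display row."""

    start: int
    end: int
    strand: str
    umi: str
    row: int


@dataclass(frozen=True)
class IsoformTrackDatum:
    """One transcript: name, clipped exon intervals, strand."""

    transcript_name: str
    exons: Tuple[Tuple[int, int], ...]
    strand: str


def build_qc_table(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """One row per cell with identity columns plus the full QC metric set.

    Missing metrics are filled with 0 and the cell is flagged; ratio columns
    are derived here from the raw tallies so they stay consistent.
    """
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated cell_id in QC table input")
    rows = []
    for c in cells:
        m = dict(c.metrics)
        flags = list(c.flags)
        base = {
            "total_reads": m.get("reads_assigned", m.get("total_reads", None)),
            "reads_mapped_to_genome": m.get(
                "reads_mapped", m.get("reads_mapped_to_genome", None)
            ),
            "reads_mapped_to_genes": m.get("reads_mapped_to_genes", None),
            "total_umis": m.get("total_umis", None),
            "mito_umis": m.get("mito_umis", None),
            "protein_coding_umis": m.get("protein_coding_umis", None),
            "genes_detected": m.get("genes_detected", None),
            "protein_coding_genes_detected": m.get(
                "protein_coding_genes_detected", None
            ),
            "reads_per_umi_median": m.get("reads_per_umi_median", None),
            "reads_per_umi_mean": m.get("reads_per_umi_mean", None),
            "reads_per_corrected_umi_median": m.get(
                "reads_per_corrected_umi_median", None
            ),
            "reads_per_corrected_umi_mean": m.get(
                "reads_per_corrected_umi_mean", None
            ),
            "genes_per_million_reads": m.get("genes_per_million_reads", None),
        }
        for key, value in base.items():
            if value is None:
                base[key] = 0.0
                if "missing_metrics" not in flags:
                    flags.append("missing_metrics")

        def ratio(num: float, den: float) -> float:
            return num / den if den else 0.0

        row: Dict[str, object] = {
            "cell_id": c.cell_id,
            "experiment_id": c.experiment_id,
            "barcode": c.barcode,
            **base,
            "fraction_mapped_to_genome": ratio(
                base["reads_mapped_to_genome"], base["total_reads"]
            ),
            "fraction_gene_reads_of_mapped": ratio(
                base["reads_mapped_to_genes"], base["reads_mapped_to_genome"]
            ),
            "fraction_gene_reads_of_total": ratio(
                base["reads_mapped_to_genes"], base["total_reads"]
            ),
            "fraction_mito_umis": ratio(base["mito_umis"], base["total_umis"]),
            "fraction_protein_coding_genes": ratio(
                base["protein_coding_genes_detected"], base["genes_detected"]
            ),
            "fraction_protein_coding_umis": ratio(
                base["protein_coding_umis"], base["total_umis"]
            ),
            "flags": ";".join(flags),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    lead = ["cell_id", "experiment_id", "barcode"]
    return table[lead + list(QC_METRIC_COLUMNS) + ["flags"]]


def qc_plot_data(
    table: pd.DataFrame,
) -> Dict[str, Dict[str, np.ndarray]]:
    """metric -> experiment_id -> per-cell values, in table order."""
    if table.empty:
        raise ValueError("QC table is empty")
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for metric in QC_METRIC_COLUMNS:
        per_exp: Dict[str, np.ndarray] = {}
        for exp, sub in table.groupby("experiment_id", sort=False):
            per_exp[str(exp)] = sub[metric].to_numpy(dtype=float)
        out[metric] = per_exp
    return out


def qc_plots(
    table: pd.DataFrame,
    out_path: os.PathLike | str,
    jitter_seed: int = 0,
) -> Path:
    """Render one boxplot panel per metric (one box per experiment, cells
    overlaid as jittered points) into a multi-page PDF, or a directory of
    SVGs when ``out_path`` has no ``.pdf`` suffix."""
    data = qc_plot_data(table)
    rng = np.random.default_rng(jitter_seed)
    out_path = Path(out_path)

    def draw(metric: str, per_exp: Dict[str, np.ndarray], ax) -> None:
        labels = list(per_exp)
        values = [per_exp[k] for k in labels]
        ax.boxplot(values, tick_labels=labels, whis=1.5, showfliers=False)
        for i, vals in enumerate(values, start=1):
            x = i + rng.uniform(-0.15, 0.15, size=len(vals))
            ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)

    if out_path.suffix == ".pdf":
        with PdfPages(out_path) as pdf:
            for metric, per_exp in data.items():
                fig, ax = plt.subplots(figsize=(6, 4))
                draw(metric, per_exp, ax)
                fig.tight_layout()
                pdf.savefig(fig)
                plt.close(fig)
    else:
        out_path.mkdir(parents=True, exist_ok=True)
        for metric, per_exp in data.items():
            fig, ax = plt.subplots(figsize=(6, 4))
            draw(metric, per_exp, ax)
            fig.tight_layout()
            fig.savefig(out_path / f"{metric}.svg")
            plt.close(fig)
    return out_path


def _first_fit_rows(
    spans: Sequence[Tuple[int, int]],
) -> List[int]:
    """Greedy first-fit packing: assign each span the lowest row where it
    does not overlap any span already in that row."""
    row_ends: List[int] = []  # rightmost end per row
    rows: List[int] = []
    for start, end in spans:
        placed = False
        for r, rend in enumerate(row_ends):
            if start >= rend:
                row_ends[r] = end
                rows.append(r)
                placed = True
                break
        if not placed:
            row_ends.append(end)
            rows.append(len(row_ends) - 1)
    return rows


def rview_data(
    alignment_path: os.PathLike | str,
    chrom: str,
    start: int,
    end: int,
) -> List[ReadTrackDatum]:
    """Every primary alignment overlapping [start, end) as one arrow datum.

    The UMI is parsed from the read name; spliced reads are drawn as a
    single arrow spanning min-start to max-end of their blocks.  Rows are
    packed greedily so arrows in one row never collide.  An unknown
    chromosome yields an empty track.
    """
    path = Path(alignment_path)
    mode = "rb" if path.suffix == ".bam" else "r"
    spans: List[Tuple[int, int, str, str]] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != chrom:
                continue
            blocks = cigar_blocks(rec.reference_start, rec.cigartuples or [])
            if not blocks:
                continue
            rstart, rend = blocks[0][0], blocks[-1][1]
            if rstart < end and rend > start:
                _, umi = parse_umi_tag(rec.query_name)
                spans.append((rstart, rend, "-" if rec.is_reverse else "+", umi))
    spans.sort(key=lambda s: (s[0], s[1]))
    rows = _first_fit_rows([(s[0], s[1]) for s in spans])
    return [
        ReadTrackDatum(start=s, end=e, strand=st, umi=u, row=r)
        for (s, e, st, u), r in zip(spans, rows)
    ]


def gview_data(
    models: GeneModelSet,
    chrom: str,
    start: int,
    end: int,
) -> List[IsoformTrackDatum]:
    """One datum per transcript with at least one exon overlapping the
    region; exons are clipped to the region for display."""
    out: List[IsoformTrackDatum] = []
    for gene in models:
        if gene.chrom != chrom:
            continue
        for tx_name, exons in gene.transcripts.items():
            clipped = tuple(
                (max(s, start), min(e, end))
                for s, e in exons
                if s < end and e > start
            )
            if clipped:
                out.append(
                    IsoformTrackDatum(
                        transcript_name=tx_name, exons=clipped, strand=gene.strand
                    )
                )
    return out


_PALETTE = [plt.get_cmap("tab20")(i) for i in range(20)]


def umi_color(umi: str) -> tuple:
    """Deterministic UMI -> color: identical UMIs share a color everywhere."""
    digest = hashlib.sha1(umi.encode("ascii")).digest()
    return _PALETTE[digest[0] % len(_PALETTE)]


def combine_tracks(
    read_track: Sequence[ReadTrackDatum],
    isoform_track: Sequence[IsoformTrackDatum],
    out_path: os.PathLike | str,
    chrom: str = "",
    region: Optional[Tuple[int, int]] = None,
) -> Path:
    """Render reads (arrows colored by UMI) above isoforms (grey exon boxes)
    with a shared x-axis in 1-based display coordinates."""
    if region is not None:
        lo, hi = region
        for d in read_track:
            if d.end <= lo or d.start >= hi:
                raise ValueError("read track datum outside the stated region")
    fig, (ax_r, ax_g) = plt.subplots(
        2, 1, figsize=(8, 6), sharex=True, height_ratios=[3, 1]
    )
    for d in read_track:
        y = d.row
        x0, x1 = (d.start + 1, d.end + 1)  # display 1-based
        if d.strand == "-":
            x0, x1 = x1, x0
        ax_r.annotate(
            "",
            xy=(x1, y),
            xytext=(x0, y),
            arrowprops=dict(arrowstyle="->", color=umi_color(d.umi), lw=1.2),
        )
    ax_r.set_ylim(-1, max((d.row for d in read_track), default=0) + 1)
    ax_r.set_ylabel("reads")
    for i, iso in enumerate(isoform_track):
        for s, e in iso.exons:
            ax_g.add_patch(
                plt.Rectangle((s + 1, i - 0.3), e - s, 0.6, color="grey")
            )
        if iso.exons:
            ax_g.plot(
                [iso.exons[0][0] + 1, iso.exons[-1][1] + 1], [i, i], color="grey", lw=0.8
            )
        label_x = iso.exons[0][0] + 1 if iso.exons else 0
        ax_g.text(label_x, i + 0.35, iso.transcript_name, fontsize=7)
    ax_g.set_ylim(-1, len(isoform_track) + 0.5)
    ax_g.set_ylabel("isoforms")
    ax_g.set_xlabel(f"{chrom} position (1-based)")
    if region is not None:
        ax_g.set_xlim(region[0] + 1, region[1] + 1)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
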