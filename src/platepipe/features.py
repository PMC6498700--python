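"""Gene annotation model: GTF parsing, exon unions, interval overlap index.

Only ``exon`` features are consumed; the exon union of each gene (the merge
of all exon intervals over all of its transcripts) is the substrate for
union-mode read assignment.  GTF coordinates (1-based inclusive) are
converted to the internal 0-based half-open convention at parse time.
"""

from __future__ import annotations

import bisect
import gzip
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .core import GeneModel

__all__ = [
    "GeneModelSet",
    "GtfFormatError",
    "exon_union",
    "load_gene_models",
    "DEFAULT_MITO_NAMES",
    "DEFAULT_SPIKE_PREFIX",
]

DEFAULT_MITO_NAMES = frozenset({"MT", "chrM", "mt"})
DEFAULT_SPIKE_PREFIX = "ERCC-"
MITO_NAME_PREFIX = "mt-"


class GtfFormatError(ValueError):
    pass


def exon_union(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Minimal sorted disjoint cover of a set of half-open intervals.

    Adjacent (touching) intervals are merged: ``[0,5)+[5,10) -> [0,10)``.
    """
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for start, end in ivs:
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


class _ChromIndex:
    """Interval index over one chromosome's exon-union intervals.

    Intervals sorted by start with a running prefix-maximum of ends; a
    query walks left from the insertion point and stops once the prefix
    maximum falls at or below the query start.
    """

    def __init__(self, intervals: List[Tuple[int, int, str, str]]) -> None:
        # (start, end, gene_id, strand)
        self.items = sorted(intervals)
        self.starts = [it[0] for it in self.items]
        self.prefix_max_end: List[int] = []
        running = 0
        for it in self.items:
            running = max(running, it[1])
            self.prefix_max_end.append(running)

    def overlapping(self, start: int, end: int) -> List[Tuple[str, str]]:
        """(gene_id, strand) pairs whose interval overlaps [start, end)."""
        hi = bisect.bisect_left(self.starts, end)
        out: List[Tuple[str, str]] = []
        i = hi - 1
        while i >= 0:
            if self.prefix_max_end[i] <= start:
                break
            s, e, gid, strand = self.items[i]
            if e > start:
                out.append((gid, strand))
            i -= 1
        out.reverse()
        return out


@dataclass
class GeneModelSet:
    """All gene models of an annotation plus a per-chromosome overlap index."""

    genes: Dict[str, GeneModel]
    gene_order: List[str]
    mito_chroms: Set[str] = field(default_factory=lambda: set(DEFAULT_MITO_NAMES))
    spike_prefix: str = DEFAULT_SPIKE_PREFIX
    _index: Dict[str, _ChromIndex] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._build_index()

    def _build_index(self) -> None:
        per_chrom: Dict[str, List[Tuple[int, int, str, str]]] = {}
        for gid in self.gene_order:
            g = self.genes[gid]
            for start, end in g.exon_union:
                per_chrom.setdefault(g.chrom, []).append((start, end, gid, g.strand))
        self._index = {c: _ChromIndex(ivs) for c, ivs in per_chrom.items()}

    def lookup(self, chrom: str, start: int, end: int) -> List[Tuple[str, str]]:
        """Distinct (gene_id, strand) whose exon union overlaps [start, end)."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        seen: Dict[str, str] = {}
        for gid, strand in idx.overlapping(start, end):
            seen.setdefault(gid, strand)
        return list(seen.items())

    def is_mito(self, gene: GeneModel) -> bool:
        return gene.chrom in self.mito_chroms or gene.gene_name.startswith(
            MITO_NAME_PREFIX
        )

    def __iter__(self):
        for gid in self.gene_order:
            yield self.genes[gid]

    def __len__(self) -> int:
        return len(self.gene_order)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_gene_models(
    gtf_path: os.PathLike | str,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    mito_names: Optional[Set[str]] = None,
) -> GeneModelSet:
    """Parse a GTF (Ensembl dialect, GENCODE tolerated) into a GeneModelSet.

    Genes appear in GTF encounter order.  ``gene_name`` defaults to the
    gene id and ``gene_biotype`` (or GENCODE ``gene_type``) to ``""`` when
    absent.  A gene is a spike-in iff its id starts with ``spike_prefix``.

    Raises
    ------
    GtfFormatError
        On an exon with end < start or a missing gene_id/transcript_id,
        with the offending line number.
    """
    mito = set(mito_names) if mito_names is not None else set(DEFAULT_MITO_NAMES)
    opener = gzip.open if str(gtf_path).endswith(".gz") else open

    # gene_id -> accumulated info
    order: List[str] = []
    info: Dict[str, Dict[str, object]] = {}

    with opener(gtf_path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from None
            if end1 < start1:
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: exon end {end1} < start {start1}"
                )
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise GtfFormatError(f"{gtf_path}: line {lineno}: missing gene_id")
            tx_id = attributes.get("transcript_id")
            if not tx_id:
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: missing transcript_id"
                )
            if strand not in ("+", "-"):
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: invalid strand {strand!r}"
                )
            interval = (start1 - 1, end1)  # 1-based inclusive -> 0-based half-open
            if gene_id not in info:
                order.append(gene_id)
                info[gene_id] = {
                    "chrom": chrom,
                    "strand": strand,
                    "gene_name": attributes.get("gene_name", gene_id),
                    "biotype": attributes.get(
                        "gene_biotype", attributes.get("gene_type", "")
                    ),
                    "transcripts": {},
                }
            rec = info[gene_id]
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfFormatError(
                    f"{gtf_path}: line {lineno}: gene {gene_id} spans multiple "
                    "chromosomes or strands"
                )
            tx_name = attributes.get("transcript_name", tx_id)
            rec["transcripts"].setdefault(tx_name, []).append(interval)  # type: ignore[union-attr]

    genes: Dict[str, GeneModel] = {}
    for gid in order:
        rec = info[gid]
        transcripts = {
            name: sorted(ivs) for name, ivs in rec["transcripts"].items()  # type: ignore[union-attr]
        }
        union = exon_union(
            iv for ivs in transcripts.values() for iv in ivs
        )
        genes[gid] = GeneModel(
            gene_id=gid,
            gene_name=str(rec["gene_name"]),
            biotype=str(rec["biotype"]),
            chrom=str(rec["chrom"]),
            strand=str(rec["strand"]),
            exon_union=union,
            transcripts=transcripts,
            is_spike_in=gid.startswith(spike_prefix),
        )
    return GeneModelSet(
        genes=genes, gene_order=order, mito_chroms=mito, spike_prefix=spike_prefix
    )
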