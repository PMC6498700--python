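"""Demultiplex paired-end FASTQ into per-cell transcript FASTQ files.

Read 1 carries the cell barcode and UMI; read 2 carries the transcript
sequence.  Pairs are filtered on barcode+UMI base quality, then matched
against a barcode whitelist by Hamming distance; assigned read-2 records are
written (optionally trimmed) with the UMI encoded in the read header as
``<id>:UMI:<seq>`` so any aligner that preserves read names keeps the tag.
"""

from __future__ import annotations

import gzip
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import VALID_BASES, CellRecord, ReadLayout

__all__ = [
    "DemuxParams",
    "DemuxStats",
    "BarcodeMatch",
    "MATCH_UNMATCHED",
    "MATCH_AMBIGUOUS",
    "extract_barcode_umi",
    "passes_quality",
    "hamming",
    "match_barcode",
    "tag_header_with_umi",
    "parse_umi_tag",
    "read_whitelist",
    "demultiplex_run",
    "ReadStructureError",
    "PairingError",
    "FastqFormatError",
]

UMI_SEP = ":UMI:"


class ReadStructureError(ValueError):
    """Read 1 too short to cover the configured barcode/UMI spans."""


class PairingError(ValueError):
    """R1/R2 record counts or ids disagree."""


class FastqFormatError(ValueError):
    """Malformed FASTQ record."""


@dataclass(frozen=True)
class DemuxParams:
    """Filtering parameters for a demultiplexing run."""

    layout: ReadLayout
    min_phred: int = 10
    max_mismatch: int = 1
    phred_offset: int = 33
    quality_rule: str = "min_base"  # or "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.min_phred <= 93:
            raise ValueError("min_phred must be in [0, 93]")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.max_mismatch >= self.layout.barcode_length:
            raise ValueError("max_mismatch must be < barcode_length")
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")
        if self.quality_rule not in ("min_base", "mean"):
            raise ValueError("quality_rule must be 'min_base' or 'mean'")


@dataclass
class DemuxStats:
    """Per-run bookkeeping; every input pair lands in exactly one bucket."""

    total_pairs: int = 0
    assigned_pairs: int = 0
    low_quality_pairs: int = 0
    unmatched_pairs: int = 0
    ambiguous_pairs: int = 0
    per_cell_assigned: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.total_pairs != (
            self.assigned_pairs
            + self.low_quality_pairs
            + self.unmatched_pairs
            + self.ambiguous_pairs
        ):
            raise AssertionError("DemuxStats buckets do not sum to total_pairs")
        if sum(self.per_cell_assigned.values()) != self.assigned_pairs:
            raise AssertionError("per-cell tallies do not sum to assigned_pairs")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DemuxStats):
            return NotImplemented
        return (
            self.total_pairs == other.total_pairs
            and self.assigned_pairs == other.assigned_pairs
            and self.low_quality_pairs == other.low_quality_pairs
            and self.unmatched_pairs == other.unmatched_pairs
            and self.ambiguous_pairs == other.ambiguous_pairs
            and self.per_cell_assigned == other.per_cell_assigned
        )


def extract_barcode_umi(
    read1_seq: str, read1_qual: Sequence[int], layout: ReadLayout
) -> Tuple[str, str, List[int]]:
    """Slice barcode and UMI out of read 1 at the layout offsets.

    Returns ``(barcode, umi, combined_quals)`` where ``combined_quals`` is
    the concatenation of the barcode and UMI per-base qualities.

    Raises
    ------
    ReadStructureError
        If read 1 is shorter than the layout requires.
    """
    if len(read1_seq) < layout.min_read1_length:
        raise ReadStructureError(
            f"read 1 length {len(read1_seq)} < required {layout.min_read1_length}"
        )
    bs, be = layout.barcode_start, layout.barcode_start + layout.barcode_length
    us, ue = layout.umi_start, layout.umi_start + layout.umi_length
    barcode = read1_seq[bs:be]
    umi = read1_seq[us:ue]
    quals = list(read1_qual[bs:be]) + list(read1_qual[us:ue])
    return barcode, umi, quals


def passes_quality(
    quals: Sequence[int], min_phred: int, rule: str = "min_base"
) -> bool:
    """True iff the quality list meets ``min_phred`` under ``rule``.

    ``min_base``: every base must meet the threshold (default; one bad UMI
    base corrupts deduplication).  ``mean``: the average must meet it.
    An empty list passes vacuously.
    """
    if not quals:
        return True
    if rule == "mean":
        return sum(quals) / len(quals) >= min_phred
    return min(quals) >= min_phred


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# Sentinel outcomes for match_barcode
MATCH_UNMATCHED = "unmatched"
MATCH_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BarcodeMatch:
    index: int
    barcode: str
    distance: int


def match_barcode(
    observed: str,
    whitelist: Sequence[str],
    max_mismatch: int,
) -> Union[BarcodeMatch, str]:
    """Match an observed barcode against the whitelist by Hamming distance.

    Returns the unique whitelist entry with minimal distance ``d`` if
    ``d <= max_mismatch``; :data:`MATCH_UNMATCHED` when the minimum distance
    exceeds the threshold; :data:`MATCH_AMBIGUOUS` when two or more entries
    tie at the minimal qualifying distance.  N bases count as mismatches
    against any base (an N never matches).
    """
    best_d = max_mismatch + 1
    best_i = -1
    tie = False
    for i, wl in enumerate(whitelist):
        if len(wl) != len(observed):
            raise ValueError(
                f"whitelist barcode {wl!r} length differs from observed "
                f"{observed!r}; whitelist inconsistent with read layout"
            )
        # N in the observed read mismatches everything
        d = sum(x != y or x == "N" for x, y in zip(observed, wl))
        if d < best_d:
            best_d, best_i, tie = d, i, False
        elif d == best_d:
            tie = True
    if best_i < 0 or best_d > max_mismatch:
        return MATCH_UNMATCHED
    if tie:
        return MATCH_AMBIGUOUS
    return BarcodeMatch(best_i, whitelist[best_i], best_d)


_UMI_RE = re.compile(r"^(?P<rid>.*):UMI:(?P<umi>[ACGTN]+)$")


def tag_header_with_umi(read_id: str, umi: str) -> str:
    """Append ``:UMI:<seq>`` to a whitespace-free read id."""
    if any(ch.isspace() for ch in read_id):
        raise ValueError(f"read id contains whitespace: {read_id!r}")
    if not umi or not set(umi) <= VALID_BASES:
        raise ValueError(f"UMI contains invalid characters: {umi!r}")
    return f"{read_id}{UMI_SEP}{umi}"


def parse_umi_tag(tagged_id: str) -> Tuple[str, str]:
    """Inverse of :func:`tag_header_with_umi`; returns ``(read_id, umi)``."""
    m = _UMI_RE.match(tagged_id)
    if not m:
        raise ValueError(f"no UMI tag in read name: {tagged_id!r}")
    return m.group("rid"), m.group("umi")


def read_whitelist(path: os.PathLike | str) -> List[Tuple[str, str]]:
    """Read a whitelist TSV (columns: barcode, optional well label).

    A header row is recognized when the first field is not purely ACGTN.
    Returns ordered ``(barcode, label)`` pairs; labels default to the
    barcode itself.
    """
    entries: List[Tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            bc = fields[0].strip()
            if lineno == 1 and not set(bc) <= VALID_BASES:
                continue  # header
            if not bc or not set(bc) <= VALID_BASES:
                raise ValueError(f"{path}: line {lineno}: invalid barcode {bc!r}")
            label = fields[1].strip() if len(fields) > 1 and fields[1].strip() else bc
            entries.append((bc, label))
    if not entries:
        raise ValueError(f"{path}: empty whitelist")
    lengths = {len(b) for b, _ in entries}
    if len(lengths) != 1:
        raise ValueError(f"{path}: whitelist barcodes have mixed lengths {lengths}")
    return entries


def _open_text(path: Path) -> Iterator[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _norm_read_id(title: str) -> str:
    rid = title.split(None, 1)[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def demultiplex_run(
    fastq_r1: os.PathLike | str,
    fastq_r2: os.PathLike | str,
    whitelist: Sequence[Tuple[str, str]] | Sequence[str],
    params: DemuxParams,
    out_dir: os.PathLike | str,
    experiment_id: str = "experiment",
) -> Tuple[List[CellRecord], DemuxStats]:
    """Split a paired FASTQ run into per-cell transcript FASTQ files.

    One gzipped FASTQ per whitelist barcode is created (even if empty) under
    ``out_dir``, named ``<experiment_id>_<barcode>.fastq.gz``.  For each
    assigned pair, read 2 (trimmed to ``layout.read2_keep`` if set) is
    written with the UMI-tagged header.  The quality filter is applied
    before whitelist matching, so a pair that is both low-quality and
    unmatched is counted as low-quality.

    Returns the per-cell records (with ``reads_assigned`` and
    ``fraction_of_total`` metrics) and the run :class:`DemuxStats`.
    """
    wl: List[Tuple[str, str]] = [
        (e, e) if isinstance(e, str) else (e[0], e[1]) for e in whitelist
    ]
    barcodes = [b for b, _ in wl]
    layout = params.layout
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cells: List[CellRecord] = []
    handles = []
    for bc, label in wl:
        path = out_dir / f"{experiment_id}_{bc}.fastq.gz"
        # mtime=0 + fixed filename in the gzip header -> byte-reproducible output
        handles.append(
            gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        )
        cells.append(
            CellRecord(
                cell_id=f"{experiment_id}_{bc}",
                experiment_id=experiment_id,
                barcode=bc,
                fastq_path=path,
            )
        )

    stats = DemuxStats(per_cell_assigned={bc: 0 for bc in barcodes})
    offset = params.phred_offset
    keep = layout.read2_keep

    try:
        with _open_text(Path(fastq_r1)) as fh1, _open_text(Path(fastq_r2)) as fh2:
            it1 = FastqGeneralIterator(fh1)
            it2 = FastqGeneralIterator(fh2)
            while True:
                try:
                    rec1 = next(it1, None)
                except ValueError as exc:
                    raise FastqFormatError(
                        f"malformed FASTQ record near pair {stats.total_pairs + 1} "
                        f"in {fastq_r1}: {exc}"
                    ) from exc
                try:
                    rec2 = next(it2, None)
                except ValueError as exc:
                    raise FastqFormatError(
                        f"malformed FASTQ record near pair {stats.total_pairs + 1} "
                        f"in {fastq_r2}: {exc}"
                    ) from exc
                if rec1 is None and rec2 is None:
                    break
                if rec1 is None or rec2 is None:
                    raise PairingError("r1/r2 FASTQ files have unequal record counts")
                t1, s1, q1 = rec1
                t2, s2, q2 = rec2
                id1, id2 = _norm_read_id(t1), _norm_read_id(t2)
                if id1 != id2:
                    raise PairingError(
                        f"read id mismatch at pair {stats.total_pairs + 1}: "
                        f"{id1!r} vs {id2!r}"
                    )
                stats.total_pairs += 1
                try:
                    barcode, umi, quals = extract_barcode_umi(
                        s1, [ord(c) - offset for c in q1], layout
                    )
                except ReadStructureError:
                    stats.low_quality_pairs += 1
                    continue
                if not passes_quality(quals, params.min_phred, params.quality_rule):
                    stats.low_quality_pairs += 1
                    continue
                result = match_barcode(barcode, barcodes, params.max_mismatch)
                if result == MATCH_UNMATCHED:
                    stats.unmatched_pairs += 1
                    continue
                if result == MATCH_AMBIGUOUS:
                    stats.ambiguous_pairs += 1
                    continue
                assert isinstance(result, BarcodeMatch)
                stats.assigned_pairs += 1
                stats.per_cell_assigned[result.barcode] += 1
                seq2 = s2[:keep] if keep else s2
                qual2 = q2[:keep] if keep else q2
                tagged = tag_header_with_umi(id1, umi)
                handles[result.index].write(
                    f"@{tagged}\n{seq2}\n+\n{qual2}\n".encode("ascii")
                )
    finally:
        for h in handles:
            fileobj = h.fileobj
            h.close()
            fileobj.close()

    for cell in cells:
        n = stats.per_cell_assigned[cell.barcode]
        cell.metrics["reads_assigned"] = n
        cell.metrics["fraction_of_total"] = (
            n / stats.total_pairs if stats.total_pairs else 0.0
        )
    stats.validate()
    return cells, stats


def write_demux_stats(
    stats: DemuxStats, path: os.PathLike | str, experiment_id: str = "experiment"
) -> None:
    """Write run-level buckets plus per-cell assigned counts as TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("experiment_id\tcategory\tbarcode\tcount\n")
        for name in (
            "total_pairs",
            "assigned_pairs",
            "low_quality_pairs",
            "unmatched_pairs",
            "ambiguous_pairs",
        ):
            fh.write(f"{experiment_id}\t{name}\t.\t{getattr(stats, name)}\n")
        for bc, n in stats.per_cell_assigned.items():
            fh.write(f"{experiment_id}\tper_cell_assigned\t{bc}\t{n}\n")
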