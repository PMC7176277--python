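"""Raw reads and alignments -> deduplicated, quality-filtered 5' start events.

The method's signal is the read 5' end.  This module trims the optional
tethered-oligonucleotide anchor and enforces a minimum read length, parses
single-end SAM/BAM with a mapping-quality floor, collapses PCR duplicates on
the (contig, strand, 5'-start, aligned length) key, converts surviving reads
to start events on the plus-strand coordinate axis, and summarises start
offsets relative to the nearest catalogued site.

Preset thresholds follow the two study designs: lambda (min length 120 nt,
MAPQ >= 60) and mESC (min length 80 nt, MAPQ >= 30).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pysam
from Bio import SeqIO

from .reference_sites import SiteCatalog

#: published processing thresholds per experiment type
PRESETS = {
    "lambda": {"min_len": 120, "min_mapq": 60},
    "mesc": {"min_len": 80, "min_mapq": 30},
}


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


class AlignedRead(NamedTuple):
    contig: str
    leftmost: int        # 0-based reference start (SAM POS - 1)
    strand: str
    mapq: int
    aligned_length: int  # reference bases consumed; clips excluded
    read_id: str


class StartEvent(NamedTuple):
    contig: str
    start: int   # 5' end on the plus-strand axis
    strand: str
    read_id: str


@dataclass
class TrimReport:
    kept: int = 0
    dropped_no_anchor: int = 0
    dropped_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"kept": self.kept, "dropped_no_anchor": self.dropped_no_anchor,
                "dropped_short": self.dropped_short}


def read_fastq(path) -> list[FastqRead]:
    return [
        FastqRead(rec.id, str(rec.seq).upper(),
                  "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def _anchor_matches(seq: str, anchor: str, max_mismatch: int) -> bool:
    if len(seq) < len(anchor):
        return False
    mismatches = sum(a != b for a, b in zip(anchor, seq))
    return mismatches <= max_mismatch


def trim_and_filter(
    reads: Iterable[FastqRead],
    anchor: str = "",
    min_len: int = 1,
    max_mismatch: int = 1,
) -> tuple[list[FastqRead], TrimReport]:
    """Strip the expected 5' constant sequence and drop short reads.

    When ``anchor`` is nonempty a read must begin with it (up to
    ``max_mismatch`` mismatches) and the prefix is removed; reads shorter
    than ``min_len`` after trimming are dropped.  The length floor is
    inclusive: a read of exactly ``min_len`` nt is kept.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[FastqRead] = []
    report = TrimReport()
    for read in reads:
        seq, qual = read.sequence, read.quality
        if anchor:
            if not _anchor_matches(seq, anchor, max_mismatch):
                report.dropped_no_anchor += 1
                continue
            seq, qual = seq[len(anchor):], qual[len(anchor):]
        if len(seq) < min_len:
            report.dropped_short += 1
            continue
        kept.append(FastqRead(read.read_id, seq, qual))
        report.kept += 1
    return kept, report


def parse_alignments(path, min_mapq: int = 0) -> list[AlignedRead]:
    """Read single-end SAM/BAM into :class:`AlignedRead` records.

    Unmapped, secondary and supplementary records are discarded, as are
    records below the MAPQ floor (inclusive: mapq == min_mapq passes).
    ``aligned_length`` is the reference span from the CIGAR, so soft/hard
    clips contribute to neither start nor length.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            span = rec.reference_length
            if span is None or span < 1:
                raise ValueError(f"malformed record (no reference span): {rec.query_name}")
            out.append(AlignedRead(
                contig=rec.reference_name,
                leftmost=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                aligned_length=span,
                read_id=rec.query_name,
            ))
    return out


def five_prime_start(read: AlignedRead) -> int:
    """5' end on the plus-strand axis: leftmost for plus reads, rightmost
    aligned base for minus reads."""
    if read.strand == "+":
        return read.leftmost
    return read.leftmost + read.aligned_length - 1


def dedup(reads: Sequence[AlignedRead], strand_aware: bool = True) -> list[AlignedRead]:
    """Collapse PCR duplicates.

    Reads sharing an identical 5' start coordinate and aligned length (and
    contig; strand by default) are duplicates and only the first in input
    order is retained.  Idempotent and order-deterministic.
    """
    seen: set[tuple] = set()
    out: list[AlignedRead] = []
    for read in reads:
        key = (read.contig, read.strand if strand_aware else ".",
               five_prime_start(read), read.aligned_length)
        if key in seen:
            continue
        seen.add(key)
        out.append(read)
    return out


def to_start_events(reads: Iterable[AlignedRead]) -> list[StartEvent]:
    return [StartEvent(r.contig, five_prime_start(r), r.strand, r.read_id) for r in reads]


def offset_histogram(
    events: Iterable[StartEvent],
    catalog: SiteCatalog,
    max_dist: int = 15,
) -> dict:
    """Histogram of signed distances from each event to its nearest
    same-strand site (read orientation; negative = start upstream of the
    site).  Events with no site within ±max_dist fall in the "far" bin; the
    histogram sums to the event count.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    if len(catalog) == 0:
        raise ValueError("empty site catalog")
    counts: Counter = Counter()
    for ev in events:
        offset = catalog.nearest_offset(ev.contig, ev.start, ev.strand)
        if offset is None or abs(offset) > max_dist:
            counts["far"] += 1
        else:
            counts[offset] += 1
    return dict(counts)


def events_to_bed(events: Iterable[StartEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.contig}\t{ev.start}\t{ev.start + 1}\t{ev.read_id}\t0\t{ev.strand}\n")


def events_from_bed(path) -> list[StartEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            contig, start, _end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            events.append(StartEvent(contig, int(start), strand, name))
    return events
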