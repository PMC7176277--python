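"""Reference genomes and catalogs of candidate target cytosines.

TOP-seq methods read out covalently labelled cytosines by counting sequencing
reads whose 5' end falls exactly on (or a few nucleotides before) the target
base.  Everything downstream of alignment is therefore defined over a catalog
of candidate sites: the two cytosines of every CG dinucleotide, the subset of
CGs embedded in the GCGC (HhaI/Hin6I) tetranucleotide used in the lambda
model system, and cytosines in non-CG (CH, H = A/C/T) context split into
CHG/CHH classes.

Coordinates are 0-based throughout.  A minus-strand site is addressed by the
plus-strand coordinate of its cytosine (i.e. the G of the plus-strand
dinucleotide), so both strands share one coordinate axis.  N bases break
motifs: no site is emitted whose defining bases include an N.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Ordered map of contig name -> uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def strand_base(self, contig: str, pos: int, strand: str) -> str:
        """Base at ``pos`` read on ``strand`` (minus-strand bases complemented)."""
        base = self.contigs[contig][pos]
        return base if strand == "+" else base.translate(COMPLEMENT)

    def strand_slice(self, contig: str, pos: int, length: int, strand: str) -> str:
        """``length`` bases in read orientation starting at ``pos`` on ``strand``.

        On the minus strand read orientation runs toward decreasing plus-axis
        coordinates; the returned string is the reverse complement of the
        corresponding plus-strand window.  Truncated at contig bounds.
        """
        seq = self.contigs[contig]
        if strand == "+":
            return seq[pos : pos + length]
        lo = max(0, pos - length + 1)
        return revcomp(seq[lo : pos + 1])


def read_fasta(path) -> GenomeSequence:
    """Load a (multi-)FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate contig names and non-IUPAC characters
    are fatal.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name in FASTA: {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

class SiteRecord(NamedTuple):
    contig: str
    pos: int            # 0-based, plus-strand axis coordinate of the C
    strand: str         # "+" or "-"
    context_class: str  # "CG", "CHG" or "CHH"
    motif_context: bool = False  # True when the CG sits inside a GCGC motif

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


@dataclass
class SiteCatalog:
    """Sorted, duplicate-free collection of candidate sites with per-strand
    nearest-site indexes."""

    records: list[SiteRecord]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(set(self.records), key=lambda r: (r.contig, r.pos, r.strand))
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, pos, strand) in site catalog")
        self._by_strand: dict[tuple[str, str], list[int]] = {}
        for rec in self.records:
            self._by_strand.setdefault((rec.contig, rec.strand), []).append(rec.pos)
        for positions in self._by_strand.values():
            positions.sort()
        self._keyset = frozenset(keys)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.records)

    def __contains__(self, key) -> bool:
        if isinstance(key, SiteRecord):
            key = key.key
        return key in self._keyset

    def positions(self, contig: str, strand: str) -> list[int]:
        return self._by_strand.get((contig, strand), [])

    def nearest_offset(self, contig: str, pos: int, strand: str) -> int | None:
        """Signed distance, in read orientation, from the nearest same-strand
        site to ``pos`` (negative = ``pos`` upstream of the site).

        Returns None when the (contig, strand) holds no sites.  Ties between
        two equidistant sites resolve to the upstream (negative) offset.
        """
        positions = self.positions(contig, strand)
        if not positions:
            return None
        i = bisect.bisect_left(positions, pos)
        candidates = []
        if i < len(positions):
            candidates.append(positions[i])
        if i > 0:
            candidates.append(positions[i - 1])
        offsets = [pos - p if strand == "+" else p - pos for p in candidates]
        offsets.sort(key=lambda o: (abs(o), o))
        return offsets[0]

    def subset(self, predicate) -> "SiteCatalog":
        return SiteCatalog([r for r in self.records if predicate(r)], dict(self.lengths))

    def to_bed(self, path) -> None:
        """Export as 6-column BED (name = context class, score = 0)."""
        with open(path, "w") as fh:
            for rec in self.records:
                name = "GCGC" if rec.motif_context else rec.context_class
                fh.write(
                    f"{rec.contig}\t{rec.pos}\t{rec.pos + 1}\t{name}\t0\t{rec.strand}\n"
                )


def find_cg_sites(genome: GenomeSequence) -> SiteCatalog:
    """All CG-dinucleotide cytosines, one site per strand per locus.

    A plus-strand CG at (i, i+1) yields the plus-strand site at i and the
    minus-strand site at i+1 (the palindromic partner).  Sites whose CG is
    embedded in a GCGC motif carry the motif flag, so the GCGC catalog is a
    true subset of this one.
    """
    records: list[SiteRecord] = []
    for contig, seq in genome.contigs.items():
        in_motif = {r.key for r in find_gcgc_sites(
            GenomeSequence({contig: seq}))} if "GCGC" in seq else set()
        i = seq.find("CG")
        while i != -1:
            records.append(SiteRecord(contig, i, "+", "CG",
                                      (contig, i, "+") in in_motif))
            records.append(SiteRecord(contig, i + 1, "-", "CG",
                                      (contig, i + 1, "-") in in_motif))
            i = seq.find("CG", i + 1)
    return SiteCatalog(records, genome.lengths)


def find_gcgc_sites(genome: GenomeSequence) -> SiteCatalog:
    """The internal CG of every GCGC motif occurrence (both strands).

    GCGC is its own reverse complement, so each plus-strand occurrence at
    offset i yields the plus-strand site at i+1 and the minus-strand site at
    i+2.  Overlapping occurrences all count, matching restriction-site
    conventions.
    """
    records: list[SiteRecord] = []
    for contig, seq in genome.contigs.items():
        i = seq.find("GCGC")
        while i != -1:
            records.append(SiteRecord(contig, i + 1, "+", "CG", True))
            records.append(SiteRecord(contig, i + 2, "-", "CG", True))
            i = seq.find("GCGC", i + 1)
    return SiteCatalog(records, genome.lengths)


def count_gcgc_loci(genome: GenomeSequence) -> int:
    """Number of GCGC motif occurrences (loci, not per-strand sites)."""
    total = 0
    for seq in genome.contigs.values():
        i = seq.find("GCGC")
        while i != -1:
            total += 1
            i = seq.find("GCGC", i + 1)
    return total


def find_ch_sites(genome: GenomeSequence) -> SiteCatalog:
    """All cytosines in CH context (H = A/C/T), classed CHG or CHH.

    Classification needs the two bases 3' of the C on its own strand; sites
    whose context window contains N or runs off the contig are skipped.
    """
    records: list[SiteRecord] = []
    for contig, seq in genome.contigs.items():
        n = len(seq)
        for i, base in enumerate(seq):
            if base == "C":
                if i + 2 >= n:
                    continue
                nxt, nxt2 = seq[i + 1], seq[i + 2]
                if nxt == "G" or nxt == "N" or nxt2 == "N":
                    continue
                cls = "CHG" if nxt2 == "G" else "CHH"
                records.append(SiteRecord(contig, i, "+", cls))
            elif base == "G":
                # minus-strand C at plus coordinate i; its downstream runs
                # toward decreasing coordinates
                if i - 2 < 0:
                    continue
                nxt = seq[i - 1].translate(COMPLEMENT)
                nxt2 = seq[i - 2].translate(COMPLEMENT)
                if nxt == "G" or nxt == "N" or nxt2 == "N":
                    continue
                cls = "CHG" if nxt2 == "G" else "CHH"
                records.append(SiteRecord(contig, i, "-", cls))
    return SiteCatalog(records, genome.lengths)


def has_downstream_cg(genome: GenomeSequence, site: SiteRecord, k: int = 7) -> bool:
    """True when a CG dinucleotide begins within the ``k`` nt 3' of ``site``
    on the site's strand.

    This is the guard against imprecise priming from a nearby CG: a candidate
    CH call with a CG starting at strand positions site+1 .. site+k is
    excluded from non-CG calling (default k = 7).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = genome.contigs.get(site.contig)
    if seq is None or not (0 <= site.pos < len(seq)):
        raise ValueError(f"site {site} outside contig bounds")
    # window of k+2 strand-oriented bases starting at the site covers CGs
    # beginning at offsets 1..k
    window = genome.strand_slice(site.contig, site.pos, k + 2, site.strand)
    return window.find("CG", 1, k + 2) != -1
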