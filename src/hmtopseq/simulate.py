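"""Synthetic TOP-seq libraries with known per-site hydroxymethylation truth.

The generator emulates the two study designs used to validate the method:

* a lambda-like titration — a small genome whose GCGC-context CGs carry a
  single hydroxymethylation level (2.5%, 5%, 10%, 20% or 40%), so median
  site coverage can be regressed on the level; and
* mESC-like libraries — reads over the full CG (and CH) catalog with
  heterogeneous per-site levels, plus unlabelled control libraries whose
  reads prime uniformly at random.

Each read is drawn independently: with probability ``background_frac`` it is
a background read (uniform start and strand); otherwise a site read whose
source site is drawn with probability proportional to its hydroxymethylation
level h, whose 5' start sits at the site shifted by an offset drawn from
``offset_dist`` (read orientation; negative = upstream, matching the
observed minor -1..-4 tail of start positions), and whose length is normal
with a floor.  A configured fraction of the library is then re-emitted
verbatim as PCR duplicates.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference_sites import (
    GenomeSequence,
    SiteCatalog,
    SiteRecord,
    find_gcgc_sites,
    revcomp,
)

FIXED_QUALITY_CHAR = "I"  # Phred 40, Sanger encoding

TITRATION_LEVELS = (0.025, 0.05, 0.10, 0.20, 0.40)

# Default start-offset distribution: the bulk of reads start exactly at the
# target cytosine with a minor tail at -1..-4 (upstream in read orientation).
DEFAULT_OFFSET_DIST = {0: 0.93, -1: 0.03, -2: 0.02, -3: 0.01, -4: 0.01}


@dataclass
class SimulationConfig:
    """Library model.

    Two sampling modes share the offset/length/background machinery:

    * per-read (``copies=None``, default): each site read picks its source
      site with probability proportional to h — the simple linear model;
    * capture-pool (``copies`` set): the library first captures a finite
      pool of distinct labeled molecules, ~Binomial(copies, h*e) per site,
      each with its own fragmentation identity (offset, length); sequencing
      then draws ``n_reads`` from the pool with replacement, so repeat
      draws are PCR duplicates.  Unique molecule recovery — what survives
      duplicate collapse — is then an increasing, saturating function of
      the modification level, which is how median site coverage responds
      to the titration in the real protocol.

    ``efficiency`` is an optional per-site relative capture efficiency
    (enzymatic labelling and pulldown vary site to site); it multiplies h.
    ``library_seed`` fixes the captured pool separately from the sequencing
    draw, so two runs with the same library_seed and different seeds are
    technical replicates of one library.
    """

    site_levels: dict[SiteRecord, float]
    n_reads: int
    offset_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_OFFSET_DIST))
    background_frac: float = 0.0
    dup_rate: float = 0.0
    read_len: tuple[float, float, int] = (150.0, 15.0, 50)  # mean, sd, min
    mapq_true: int = 60
    mapq_background: int = 20
    anchor: str = ""  # optional tethered-ODN prefix prepended to FASTQ reads
    seed: int = 0
    copies: int | None = None
    library_seed: int | None = None
    efficiency: dict[SiteRecord, float] | None = None

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        total = sum(self.offset_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"offset_dist must sum to 1, got {total}")
        for p in self.offset_dist.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("offset probabilities must lie in [0, 1]")
        if not 0.0 <= self.background_frac <= 1.0:
            raise ValueError("background_frac must lie in [0, 1]")
        if not 0.0 <= self.dup_rate < 1.0:
            raise ValueError("dup_rate must lie in [0, 1)")
        for h in self.site_levels.values():
            if not 0.0 <= h <= 1.0:
                raise ValueError("site levels must lie in [0, 1]")


class SimulatedRead(NamedTuple):
    read_id: str
    contig: str
    start: int        # 5' end, plus-strand axis
    strand: str
    length: int
    sequence: str     # as sequenced (strand orientation), without anchor
    mapq: int
    origin: str       # "site" | "background" | "duplicate"
    offset: int | None
    site_pos: int | None
    site_strand: str | None
    dup_of: str | None


def make_random_genome(
    length: int,
    seed: int,
    name: str = "sim1",
    gc: float = 0.5,
) -> GenomeSequence:
    """Uniform-composition random genome; at gc=0.5 a 50-kb sequence carries
    ~195 GCGC motifs in expectation (length / 256), close to the 215 loci of
    the lambda reference."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeSequence({name: seq})


def make_titration_levels(catalog: SiteCatalog, level: float) -> dict[SiteRecord, float]:
    """Assign one hydroxymethylation level to every GCGC-context site."""
    if len(catalog) == 0:
        raise ValueError("empty site catalog")
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    return {rec: (level if rec.motif_context else 0.0) for rec in catalog}


def _truncated_length(rng, n, mean, sd, minimum):
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.maximum(lengths, minimum)


def _effective_levels(config: SimulationConfig) -> list[tuple[SiteRecord, float]]:
    eff = config.efficiency or {}
    out = []
    for rec, h in config.site_levels.items():
        w = h * eff.get(rec, 1.0)
        if w > 0:
            out.append((rec, min(w, 1.0)))
    return out


def simulate_reads(
    genome: GenomeSequence,
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Draw a library and its truth table.

    Returns the reads (originals followed by any verbatim duplicate
    re-emissions) and a truth table with one row per read.  Deterministic
    given the seeds.
    """
    rng = np.random.default_rng(config.seed)
    sites = _effective_levels(config)
    if not sites and config.background_frac == 0.0:
        raise ValueError("no read source: all site levels zero and background_frac = 0")

    n_dup = int(round(config.dup_rate * config.n_reads))
    n_orig = config.n_reads - n_dup

    contigs = list(genome.contigs)
    contig_lengths = np.array([len(genome.contigs[c]) for c in contigs])
    contig_p = contig_lengths / contig_lengths.sum()

    is_bg = rng.random(n_orig) < config.background_frac
    mean_len, sd_len, min_len = config.read_len

    offsets_keys = np.array(sorted(config.offset_dist), dtype=int)
    offsets_p = np.array([config.offset_dist[k] for k in offsets_keys])

    n_site = int((~is_bg).sum())
    if config.copies is None:
        # per-read mode: source site ~ h, fragmentation drawn per read
        weights = np.array([h for _, h in sites], dtype=float)
        if weights.size:
            weights = weights / weights.sum()
        site_idx = rng.choice(len(sites), size=n_site, p=weights) if n_site else np.array([], int)
        site_off = rng.choice(offsets_keys, size=n_site, p=offsets_p)
        site_lengths = _truncated_length(rng, n_site, mean_len, sd_len, min_len)
        molecule_of = None
    else:
        # capture-pool mode: enumerate the library's distinct labeled
        # molecules once, then sequence the pool with replacement
        pool_rng = np.random.default_rng(
            config.seed if config.library_seed is None else config.library_seed)
        per_site = pool_rng.binomial(config.copies, [h for _, h in sites]) if sites else np.array([], int)
        mol_site = np.repeat(np.arange(len(sites)), per_site)
        n_mol = len(mol_site)
        if n_mol == 0 and config.background_frac == 0.0:
            raise ValueError("no read source: captured pool is empty and background_frac = 0")
        mol_off = pool_rng.choice(offsets_keys, size=n_mol, p=offsets_p)
        mol_len = _truncated_length(pool_rng, n_mol, mean_len, sd_len, min_len)
        if n_mol == 0:
            n_site = 0
            is_bg[:] = True
        draw = rng.integers(0, n_mol, size=n_site) if n_site else np.array([], int)
        site_idx = mol_site[draw]
        site_off = mol_off[draw]
        site_lengths = mol_len[draw]
        molecule_of = draw

    n_bg = int(is_bg.sum())
    bg_contig_idx = rng.choice(len(contigs), size=n_bg, p=contig_p)
    bg_start = rng.integers(0, contig_lengths[bg_contig_idx]) if n_bg else np.array([], int)
    bg_strand = np.where(rng.random(n_bg) < 0.5, "+", "-")
    bg_lengths = _truncated_length(rng, n_bg, mean_len, sd_len, min_len)

    reads: list[SimulatedRead] = []
    first_read_of_molecule: dict[int, str] = {}
    j_site = j_bg = 0
    for i in range(n_orig):
        rid = f"read{i:07d}"
        if is_bg[i]:
            contig = contigs[bg_contig_idx[j_bg]]
            start, strand, length = int(bg_start[j_bg]), str(bg_strand[j_bg]), int(bg_lengths[j_bg])
            origin, offset, spos, sstrand, dup_of = "background", None, None, None, None
            mapq = config.mapq_background
            j_bg += 1
        else:
            rec = sites[int(site_idx[j_site])][0]
            contig, strand, spos = rec.contig, rec.strand, rec.pos
            offset = int(site_off[j_site])
            # offset applies in read orientation: upstream (-) means a
            # smaller plus-axis coordinate on +, a larger one on -
            start = spos + offset if strand == "+" else spos - offset
            length = int(site_lengths[j_site])
            sstrand = strand
            mapq = config.mapq_true
            dup_of = None
            origin = "site"
            if molecule_of is not None:
                mol = int(molecule_of[j_site])
                if mol in first_read_of_molecule:
                    origin, dup_of = "duplicate", first_read_of_molecule[mol]
                else:
                    first_read_of_molecule[mol] = rid
            j_site += 1
        L = len(genome.contigs[contig])
        start = min(max(start, 0), L - 1)
        # truncate at the contig end the read runs toward
        length = min(length, L - start) if strand == "+" else min(length, start + 1)
        sequence = genome.strand_slice(contig, start, length, strand)
        reads.append(SimulatedRead(
            rid, contig, start, strand, length, sequence, mapq,
            origin, offset, spos, sstrand, dup_of,
        ))

    if n_dup:
        dup_src = rng.integers(0, n_orig, size=n_dup)
        for j, src in enumerate(dup_src):
            orig = reads[int(src)]
            reads.append(orig._replace(
                read_id=f"dup{j:07d}", origin="duplicate", dup_of=orig.read_id,
            ))

    truth = pd.DataFrame(reads, columns=SimulatedRead._fields).astype(
        {"offset": "Int64", "site_pos": "Int64"}
    ).drop(columns=["sequence"])
    return reads, truth


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_library(
    reads: Sequence[SimulatedRead],
    truth: pd.DataFrame,
    genome: GenomeSequence,
    fastq_path=None,
    sam_path=None,
    truth_path=None,
    anchor: str = "",
) -> None:
    """Write FASTQ (fixed quality), coordinate-sorted SAM and truth TSV.

    SAM records are clip-free (full-length match CIGAR) so parsed 5' starts
    round-trip exactly to the truth starts.  Minus-strand reads are stored in
    forward-genome orientation with the reverse flag, per SAM convention.
    """
    if not reads:
        raise ValueError("empty read set")
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for r in reads:
                seq = anchor + r.sequence
                fh.write(f"@{r.read_id}\n{seq}\n+\n{FIXED_QUALITY_CHAR * len(seq)}\n")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    if sam_path is not None:
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths.items()],
        })
        tid = {name: i for i, name in enumerate(genome.lengths)}
        records = []
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_id = tid[r.contig]
            leftmost = r.start if r.strand == "+" else r.start - r.length + 1
            a.reference_start = leftmost
            a.mapping_quality = r.mapq
            a.cigarstring = f"{r.length}M"
            a.flag = 0 if r.strand == "+" else 16
            a.query_sequence = r.sequence if r.strand == "+" else revcomp(r.sequence)
            a.query_qualities = pysam.qualitystring_to_array(FIXED_QUALITY_CHAR * r.length)
            records.append(a)
        records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
            for a in records:
                out.write(a)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def site_efficiencies(
    catalog, seed: int, sigma: float = 0.6,
) -> dict[SiteRecord, float]:
    """Per-site relative capture efficiency, lognormal(0, sigma).

    Enzymatic labelling and pulldown efficiency vary site to site; a
    lognormal spread reproduces the order-of-magnitude per-site coverage
    range seen in replicate scatter of real libraries.  Seeded by the
    genome, not the run: efficiency is a property of the site.
    """
    rng = np.random.default_rng(seed)
    return {rec: float(rng.lognormal(0.0, sigma)) for rec in catalog}


def preset_lambda_titration(
    level: float,
    n_reads: int = 50_000,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    genome_length: int = 50_000,
    genome_seed: int = 20_000_416,
    copies: int | None = 400,
    background_frac: float = 0.01,
    efficiency_sigma: float = 0.6,
    **overrides,
) -> tuple[GenomeSequence, SimulationConfig]:
    """Lambda-style titration library: one level at every GCGC site.

    The default synthetic genome is a 50-kb uniform-composition sequence
    (~200 GCGC loci), standing in for the 48.5-kb lambda reference.  The
    capture-pool mode is on by default (400 labeled genome copies) so that
    unique-molecule coverage responds to the titration level the way the
    real protocol does; per-site lognormal efficiencies are tied to the
    genome seed and therefore shared across replicate libraries.
    """
    if genome is None:
        genome = make_random_genome(genome_length, genome_seed, name="lambda_like")
    catalog = find_gcgc_sites(genome)
    levels = make_titration_levels(catalog, level)
    eff = site_efficiencies(catalog, seed=genome_seed + 1, sigma=efficiency_sigma)
    config = SimulationConfig(
        site_levels=levels, n_reads=n_reads, read_len=(150.0, 15.0, 120),
        background_frac=background_frac, copies=copies, efficiency=eff,
        mapq_background=20, seed=seed, **overrides)
    return genome, config


def preset_control(
    n_reads: int = 50_000,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    genome_length: int = 50_000,
    genome_seed: int = 20_000_416,
    **overrides,
) -> tuple[GenomeSequence, SimulationConfig]:
    """Unlabelled control library: all levels zero, pure background priming."""
    if genome is None:
        genome = make_random_genome(genome_length, genome_seed, name="lambda_like")
    config = SimulationConfig(site_levels={}, n_reads=n_reads,
                              background_frac=1.0, seed=seed, **overrides)
    return genome, config


def preset_mesc(
    n_reads: int = 100_000,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    genome_length: int = 200_000,
    genome_seed: int = 101,
    levels_seed: int | None = None,
    level_alpha: float = 0.3,
    hydroxymethylated_frac: float = 0.25,
    background_frac: float = 0.05,
    dup_rate: float = 0.1,
    **overrides,
) -> tuple[GenomeSequence, SimulationConfig]:
    """mESC-like library: a sparse, heterogeneous subset of CG sites carries
    Beta-distributed hydroxymethylation levels; moderate background and
    duplicate rates.

    The per-site level map is seeded by ``levels_seed`` (default: derived
    from the genome seed), so libraries simulated with different run seeds
    share the same underlying truth — the replicate design.
    """
    from .reference_sites import find_cg_sites

    if genome is None:
        genome = make_random_genome(genome_length, genome_seed, name="chrS")
    catalog = find_cg_sites(genome)
    rng = np.random.default_rng(genome_seed + 7_919 if levels_seed is None else levels_seed)
    levels: dict[SiteRecord, float] = {}
    for rec in catalog:
        if rng.random() < hydroxymethylated_frac:
            levels[rec] = float(rng.beta(level_alpha, 1.0))
        else:
            levels[rec] = 0.0
    config = SimulationConfig(
        site_levels=levels, n_reads=n_reads, background_frac=background_frac,
        dup_rate=dup_rate, read_len=(120.0, 15.0, 80), mapq_true=60,
        mapq_background=10, seed=seed, **overrides,
    )
    return genome, config
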