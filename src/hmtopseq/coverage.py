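"""Per-site exact-start coverage and windowed, CG-density-normalised signal.

Counting is strict: a read contributes to a site only when its 5' start
coordinate, strand and contig all match the catalogued cytosine ("exact-start
calling").  Coverage counts are the primary signal — the protocol infers
relative, not absolute, modification levels — and the windowed h-density
(counts per CG dinucleotide locus per window, default 180 bp, log2(x+1)
transformed) is the regional summary used for replicate comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .readproc import StartEvent
from .reference_sites import SiteCatalog, SiteRecord

CONTEXT_FILTERS = {
    "CG": lambda r: r.context_class == "CG",
    "GCGC": lambda r: r.motif_context,
    "CH": lambda r: r.context_class in ("CHG", "CHH"),
    "all": lambda r: True,
}


@dataclass
class SiteCoverageTable:
    """Map of catalogued site -> exact-start read count."""

    records: tuple[SiteRecord, ...]
    counts: np.ndarray
    lengths: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.records),):
            raise ValueError("counts shape does not match records")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        self._index = {rec.key: i for i, rec in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise ValueError("duplicate sites in coverage table")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, key, default: int = 0) -> int:
        if isinstance(key, SiteRecord):
            key = key.key
        i = self._index.get(key)
        return int(self.counts[i]) if i is not None else default

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def median(self) -> float:
        return float(np.median(self.counts)) if len(self) else math.nan

    def covered_keys(self) -> set[tuple[str, int, str]]:
        return {rec.key for rec, c in zip(self.records, self.counts) if c > 0}

    def with_counts(self, counts: np.ndarray) -> "SiteCoverageTable":
        return SiteCoverageTable(self.records, counts, dict(self.lengths), dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contig": [r.contig for r in self.records],
            "pos": [r.pos for r in self.records],
            "strand": [r.strand for r in self.records],
            "context": [r.context_class for r in self.records],
            "gcgc": [r.motif_context for r in self.records],
            "count": self.counts,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for rec, c in zip(self.records, self.counts):
                fh.write(f"{rec.contig}\t{rec.pos}\t{rec.pos + 1}\t{int(c)}\n")


def read_table(path, lengths: dict[str, int] | None = None) -> SiteCoverageTable:
    """Rebuild a :class:`SiteCoverageTable` from its TSV export."""
    df = pd.read_csv(path, sep="\t")
    records = tuple(
        SiteRecord(str(r.contig), int(r.pos), str(r.strand), str(r.context), bool(r.gcgc))
        for r in df.itertuples()
    )
    return SiteCoverageTable(records, df["count"].to_numpy(np.int64), lengths or {})


def site_coverage(
    events: Iterable[StartEvent],
    catalog: SiteCatalog,
    context_filter: str = "all",
) -> SiteCoverageTable:
    """Count events whose (contig, strand, start) exactly equals a site.

    Events at any nonzero offset from a site contribute nothing.  The
    ``context_filter`` restricts the table's domain to CG, GCGC-context or
    CH sites.
    """
    try:
        pred = CONTEXT_FILTERS[context_filter]
    except KeyError:
        raise ValueError(f"unknown context filter {context_filter!r}") from None
    records = tuple(rec for rec in catalog if pred(rec))
    index = {rec.key: i for i, rec in enumerate(records)}
    counts = np.zeros(len(records), dtype=np.int64)
    for ev in events:
        i = index.get((ev.contig, ev.start, ev.strand))
        if i is not None:
            counts[i] += 1
    return SiteCoverageTable(records, counts, dict(catalog.lengths))


# ---------------------------------------------------------------------------
# h-density
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    """Tiled fixed-width windows with CG-density-normalised coverage.

    ``values`` is NaN for windows containing no CG locus — absence of sites
    is missing data, never a zero.
    """

    windows: pd.DataFrame  # columns contig, start, end, n_cg, value
    transform: str         # "raw" | "log2"
    width: int

    def to_bedgraph(self, path) -> None:
        present = self.windows.dropna(subset=["value"])
        with open(path, "w") as fh:
            for row in present.itertuples():
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.value:g}\n")


def h_density(
    table: SiteCoverageTable,
    catalog: SiteCatalog,
    w: int = 180,
    transform: str = "log2",
    phase: int = 0,
) -> DensityTrack:
    """Windowed h-density: summed site counts / number of CG dinucleotide
    loci, per non-overlapping ``w``-bp window tiled from ``phase``.

    CG density is unweighted: each CG locus (plus-strand dinucleotide
    position) counts once regardless of strand coverage.  With
    ``transform="log2"`` values become log2(density + 1); the pseudocount
    keeps zero-coverage windows finite.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    if transform not in ("raw", "log2"):
        raise ValueError(f"unknown transform {transform!r}")
    rows = []
    for contig, length in catalog.lengths.items():
        n_windows = max(1, -(-(length - phase) // w)) if length > phase else 0
        starts = phase + w * np.arange(n_windows)
        ends = np.minimum(starts + w, length)
        loci = np.array(catalog.positions(contig, "+"), dtype=int)
        loci_in = np.zeros(n_windows, dtype=int)
        if loci.size and n_windows:
            idx = (loci - phase) // w
            idx = idx[(idx >= 0) & (idx < n_windows)]
            np.add.at(loci_in, idx, 1)
        sums = np.zeros(n_windows, dtype=float)
        for rec, c in zip(table.records, table.counts):
            if rec.contig != contig or c == 0:
                continue
            j = (rec.pos - phase) // w
            if 0 <= j < n_windows:
                sums[j] += c
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(loci_in > 0, sums / np.maximum(loci_in, 1), np.nan)
        if transform == "log2":
            vals = np.where(np.isnan(vals), np.nan, np.log2(vals + 1.0))
        for s, e, n_cg, v in zip(starts, ends, loci_in, vals):
            rows.append((contig, int(s), int(e), int(n_cg), v))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "n_cg", "value"])
    return DensityTrack(df, transform, w)


# ---------------------------------------------------------------------------
# Subsampling / correlation / region totals
# ---------------------------------------------------------------------------

def subsample(table: SiteCoverageTable, fraction: float, seed: int) -> SiteCoverageTable:
    """Binomial thinning: each assigned read kept independently with
    probability ``fraction`` (the in-silico subsampling used for replicate
    saturation analysis)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = rng.binomial(table.counts, fraction)
    return table.with_counts(kept.astype(np.int64))


@dataclass
class CorrelationSummary:
    scope: str
    r: float | None = None
    per_contig: dict[str, float] = field(default_factory=dict)
    mean: float | None = None
    sd: float | None = None
    n: int = 0


def _paired_values(a, b) -> pd.DataFrame:
    """Align two signals (coverage tables or density tracks) on their shared
    non-missing positions."""
    if isinstance(a, SiteCoverageTable) and isinstance(b, SiteCoverageTable):
        fa, fb = a.to_frame(), b.to_frame()
        keys = ["contig", "pos", "strand"]
        m = fa.merge(fb, on=keys, suffixes=("_a", "_b"))
        return pd.DataFrame({"contig": m["contig"], "x": m["count_a"], "y": m["count_b"]})
    if isinstance(a, DensityTrack) and isinstance(b, DensityTrack):
        keys = ["contig", "start", "end"]
        m = a.windows.merge(b.windows, on=keys, suffixes=("_a", "_b"))
        m = m.dropna(subset=["value_a", "value_b"])
        return pd.DataFrame({"contig": m["contig"], "x": m["value_a"], "y": m["value_b"]})
    raise TypeError("signals must both be SiteCoverageTable or both DensityTrack")


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlate(signal_a, signal_b, scope: str = "global") -> CorrelationSummary:
    """Pearson correlation on the intersection of non-missing positions.

    ``scope="per-contig"`` returns one r per contig plus their mean and sd
    (the per-autosome convention).  Fewer than 3 shared positions, or a
    constant signal, yields a missing result rather than a number.
    """
    pairs = _paired_values(signal_a, signal_b)
    if scope == "global":
        r = _pearson(pairs["x"].to_numpy(float), pairs["y"].to_numpy(float))
        return CorrelationSummary("global", r=r, n=len(pairs))
    if scope == "per-contig":
        per: dict[str, float] = {}
        for contig, grp in pairs.groupby("contig", sort=True):
            r = _pearson(grp["x"].to_numpy(float), grp["y"].to_numpy(float))
            if r is not None:
                per[contig] = r
        vals = np.array(list(per.values()))
        return CorrelationSummary(
            "per-contig", per_contig=per,
            mean=float(vals.mean()) if vals.size else None,
            sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
            n=len(pairs),
        )
    raise ValueError(f"unknown scope {scope!r}")


def region_signal(
    table: SiteCoverageTable,
    regions: pd.DataFrame,
    transform: str | None = None,
) -> pd.DataFrame:
    """Total site counts per half-open region, optionally square-root
    transformed (the summary used for comparison against low-resolution
    enrichment peak tracks)."""
    if transform not in (None, "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    frame = table.to_frame().sort_values(["contig", "pos"])
    for contig, grp in frame.groupby("contig"):
        pos = grp["pos"].to_numpy()
        csum = np.concatenate([[0], np.cumsum(grp["count"].to_numpy())])
        by_contig[contig] = (pos, csum)
    totals = []
    for row in regions.itertuples():
        entry = by_contig.get(row.contig)
        if entry is None:
            totals.append(0.0)
            continue
        pos, csum = entry
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        totals.append(float(csum[hi] - csum[lo]))
    out = regions.copy()
    out["signal"] = totals
    if transform == "sqrt":
        out["signal"] = np.sqrt(out["signal"])
    return out
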