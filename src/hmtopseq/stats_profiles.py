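"""Downstream statistics: titration regression, feature enrichment,
metagene, strand-bias and exon-intron boundary analyses.

These are the analyses that turn exact-start coverage tables into the
method's validation results: the quadratic response of median GCGC coverage
to the hydroxymethylation level, Fisher-exact enrichment of coverage groups
across annotation classes, CG-density-normalised metagene profiles, paired
sense/antisense strand comparisons per expression group, and signal
contrasts across exon-intron boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotations import FeatureSet, GeneModel
from .coverage import SiteCoverageTable
from .reference_sites import SiteCatalog, SiteRecord


# ---------------------------------------------------------------------------
# Titration regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """Quadratic OLS fit of median coverage (Y) on modification level (X)."""

    b0: float
    b1: float
    b2: float
    r_squared: float
    adj_r_squared: float
    f_pvalue: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x * x


def fit_titration(levels: Sequence[float], medians: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of Y = b0 + b1*X + b2*X^2.

    X is the per-library hydroxymethylation level and Y the median site
    coverage.  Adjusted R^2 uses p = 2 predictors:
    1 - (1-R^2)(n-1)/(n-3).  Requires at least 4 pairs and 3 distinct
    levels (otherwise the quadratic design is collinear).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(medians, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and medians must be 1-D and equally long")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 (level, median) pairs for a quadratic fit")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct levels (collinear design)")
    design = sm.add_constant(np.column_stack([x, x * x]))
    if np.ptp(y) == 0:
        return RegressionFit(float(y[0]), 0.0, 0.0, 0.0, 0.0, 1.0, n)
    fit = sm.OLS(y, design).fit()
    b0, b1, b2 = fit.params
    return RegressionFit(
        float(b0), float(b1), float(b2),
        float(fit.rsquared), float(fit.rsquared_adj), float(fit.f_pvalue), n,
    )


# ---------------------------------------------------------------------------
# Signal groups and enrichment
# ---------------------------------------------------------------------------

@dataclass
class SignalGroups:
    """Partition of covered sites into coverage-rank bands."""

    groups: dict[str, list[SiteRecord]]
    degenerate: bool = False

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.groups.items()}

    def all_sites(self) -> list[SiteRecord]:
        return [rec for members in self.groups.values() for rec in members]


#: rank-fraction bands per scheme: low, mid, high as [lo, hi) fractions
GROUP_SCHEMES = {
    # 20%-wide bands: bottom 20 / middle [40,60) / top 20
    "default": {"low": (0.0, 0.2), "mid": (0.4, 0.6), "high": (0.8, 1.0)},
    # narrower middle band [40,50)
    "methods": {"low": (0.0, 0.2), "mid": (0.4, 0.5), "high": (0.8, 1.0)},
}


def signal_groups(table: SiteCoverageTable, scheme: str = "default") -> SignalGroups:
    """Partition covered sites into low / mid / high coverage bands by rank.

    Sites are stably sorted by count (ties keep catalog order), then sliced
    at the scheme's rank fractions, so e.g. counts 1..10 give low {1,2},
    mid {5,6}, high {9,10}.  An all-equal table yields a flagged degenerate
    partition.
    """
    try:
        bands = GROUP_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown grouping scheme {scheme!r}") from None
    covered = [(rec, c) for rec, c in zip(table.records, table.counts) if c > 0]
    if not covered:
        raise ValueError("no covered sites to partition")
    order = sorted(range(len(covered)), key=lambda i: covered[i][1])  # stable
    n = len(covered)
    groups = {}
    for name, (lo, hi) in bands.items():
        groups[name] = [covered[i][0] for i in order[int(np.floor(lo * n)): int(np.floor(hi * n))]]
    degenerate = covered[0][1] == covered[-1][1] and len({c for _, c in covered}) == 1
    return SignalGroups(groups, degenerate)


@dataclass
class EnrichmentResult:
    feature: str
    group: str
    a: int  # in group, overlaps feature
    b: int  # in group, outside feature
    c: int  # other groups, overlaps feature
    d: int  # other groups, outside feature
    odds_ratio: float
    p_value: float
    degenerate: bool = False


class _IntervalMembership:
    """Point-in-union-of-intervals queries per contig (merged, half-open)."""

    def __init__(self, intervals: pd.DataFrame):
        self._bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, grp in intervals.groupby("contig"):
            merged: list[tuple[int, int]] = []
            for s, e in sorted(zip(grp["start"], grp["end"])):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            self._bounds[str(contig)] = (starts, ends)

    def __call__(self, contig: str, pos: int) -> bool:
        entry = self._bounds.get(contig)
        if entry is None:
            return False
        starts, ends = entry
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and pos < ends[i]


def feature_enrichment(partition: SignalGroups, features: FeatureSet) -> list[EnrichmentResult]:
    """Fisher's exact test of (in group) x (overlaps feature) per feature
    and coverage group, over all partitioned sites.

    The odds ratio is the cross-product ratio (a*d)/(b*c); tables with a
    zero cell report the Haldane-corrected estimate, flagged degenerate.
    The p-value is the two-sided exact (hypergeometric) probability.
    """
    if not features.labels():
        raise ValueError("empty feature set")
    universe = partition.all_sites()
    group_of: dict[tuple, str] = {}
    for name, members in partition.groups.items():
        for rec in members:
            group_of[rec.key] = name
    results = []
    for label in features.labels():
        member = _IntervalMembership(features[label])
        overlaps = {rec.key: member(rec.contig, rec.pos) for rec in universe}
        for name in partition.groups:
            a = sum(1 for rec in universe if group_of[rec.key] == name and overlaps[rec.key])
            b = sum(1 for rec in universe if group_of[rec.key] == name and not overlaps[rec.key])
            c = sum(1 for rec in universe if group_of[rec.key] != name and overlaps[rec.key])
            d = len(universe) - a - b - c
            degenerate = min(a, b, c, d) == 0
            if degenerate:
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (b * c)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            results.append(EnrichmentResult(label, name, a, b, c, d, float(odds), float(p), degenerate))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Coverage lookup helper
# ---------------------------------------------------------------------------

class _StrandedCounts:
    """Sorted per-(contig, strand) position/count arrays with prefix sums,
    for fast window totals."""

    def __init__(self, table: SiteCoverageTable):
        buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for rec, c in zip(table.records, table.counts):
            buckets.setdefault((rec.contig, rec.strand), []).append((rec.pos, int(c)))
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, items in buckets.items():
            items.sort()
            pos = np.array([p for p, _ in items])
            cnt = np.array([c for _, c in items])
            self._data[key] = (pos, cnt, np.concatenate([[0], np.cumsum(cnt)]))

    def window_sum(self, contig: str, strand: str | None, start: int, end: int) -> int:
        total = 0
        strands = ("+", "-") if strand is None else (strand,)
        for s in strands:
            entry = self._data.get((contig, s))
            if entry is None:
                continue
            pos, _, csum = entry
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            total += int(csum[hi] - csum[lo])
        return total

    def window_counts(self, contig: str, strand: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions, counts) of sites in [start, end) on one strand."""
        entry = self._data.get((contig, strand))
        if entry is None:
            return np.array([], int), np.array([], int)
        pos, cnt, _ = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], cnt[lo:hi]


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Binned signal profile: rows are genes/boundaries, columns bins or
    signed offsets; NaN marks missing cells (no CG sites in the bin)."""

    values: np.ndarray
    columns: list
    rows: list
    label: str = ""

    def column_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)


METAGENE_ELEMENTS = ("upstream", "utr5", "exon", "intron", "utr3", "downstream")


def metagene_profile(
    table: SiteCoverageTable,
    gene_models: list[GeneModel],
    catalog: SiteCatalog,
    n_bins: int = 10,
    flank: int = 2_000,
) -> dict[str, ProfileMatrix]:
    """Per gene-element profile of CG-density-normalised coverage.

    Each element instance is divided into ``n_bins`` equally sized bins by
    fractional position (bin = floor(n_bins * (pos-start)/len), clamped);
    bin value = summed site counts / number of catalogued sites in the bin.
    Minus-strand genes are traversed 5'->3' (bins reversed).  Instances
    shorter than ``n_bins`` nt are skipped with a warning.  Both strands'
    counts and sites enter each bin.
    """
    counts = _StrandedCounts(table)
    site_table = SiteCoverageTable(
        tuple(catalog.records), np.ones(len(catalog), dtype=np.int64), dict(catalog.lengths))
    density = _StrandedCounts(site_table)

    def element_intervals(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
        u5, u3 = gene.utrs()
        if gene.strand == "+":
            upstream = [(gene.start - flank, gene.start)]
            downstream = [(gene.end, gene.end + flank)]
        else:
            upstream = [(gene.end, gene.end + flank)]
            downstream = [(gene.start - flank, gene.start)]
        return {
            "upstream": upstream, "utr5": u5, "exon": gene.exons(),
            "intron": gene.introns(), "utr3": u3, "downstream": downstream,
        }

    profiles: dict[str, list[np.ndarray]] = {elem: [] for elem in METAGENE_ELEMENTS}
    row_ids: dict[str, list[str]] = {elem: [] for elem in METAGENE_ELEMENTS}
    for gene in gene_models:
        for elem, intervals in element_intervals(gene).items():
            for start, end in intervals:
                length = end - start
                if length < n_bins:
                    if length > 0:
                        warnings.warn(
                            f"{elem} of {gene.gene_id} shorter than {n_bins} nt; skipped")
                    continue
                sums = np.zeros(n_bins)
                n_sites = np.zeros(n_bins)
                edges = start + np.floor(length * np.arange(n_bins + 1) / n_bins).astype(int)
                for j in range(n_bins):
                    sums[j] = counts.window_sum(gene.contig, None, edges[j], edges[j + 1])
                    n_sites[j] = density.window_sum(gene.contig, None, edges[j], edges[j + 1])
                with np.errstate(invalid="ignore", divide="ignore"):
                    vals = np.where(n_sites > 0, sums / np.maximum(n_sites, 1), np.nan)
                if gene.strand == "-":
                    vals = vals[::-1]
                profiles[elem].append(vals)
                row_ids[elem].append(gene.gene_id)
    return {
        elem: ProfileMatrix(
            np.vstack(rows) if rows else np.empty((0, n_bins)),
            columns=list(range(n_bins)), rows=row_ids[elem], label=elem)
        for elem, rows in profiles.items()
    }


# ---------------------------------------------------------------------------
# Strand bias
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on the given differences; all-zero differences
    report (0, 1) by convention."""
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    if np.ptp(diffs) == 0:
        # equal nonzero differences: zero variance, infinitely significant
        return float(np.inf) * np.sign(diffs[0]), 0.0
    t, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
    return float(t), float(p)


def strand_bias(
    table: SiteCoverageTable,
    gene_models: list[GeneModel],
    expression: dict[str, float] | pd.Series,
    n_bins: int = 60,
    min_signal_bins: int = 20,
    length_percentiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Sense-vs-antisense coverage comparison per expression group.

    Genes outside the [1st, 99th] length percentiles are removed; each gene
    is split into ``n_bins`` bins and a gene qualifies only with signal in
    at least ``min_signal_bins`` bins on both strands.  Expression groups:
    zero-expression plus tertiles of the expressed genes.  Per group a
    two-sided paired t-test compares per-gene mean bin signal on the sense
    strand (matching gene orientation) against the antisense strand.
    Groups with fewer than 3 qualifying genes report NaN.
    """
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    counts = _StrandedCounts(table)

    lengths = np.array([g.length for g in gene_models], dtype=float)
    lo, hi = np.percentile(lengths, length_percentiles)
    genes = [g for g in gene_models if lo <= g.length <= hi]

    expressed = sorted(v for g in genes if (v := expression.get(g.gene_id, 0.0)) > 0)
    if expressed:
        t1, t2 = np.percentile(expressed, [100 / 3, 200 / 3])
    else:
        t1 = t2 = 0.0

    def group_of(gene: GeneModel) -> str:
        v = expression.get(gene.gene_id, 0.0)
        if v <= 0:
            return "zero"
        if v <= t1:
            return "low"
        if v <= t2:
            return "mid"
        return "high"

    per_gene: dict[str, list[tuple[float, float]]] = {g: [] for g in ("zero", "low", "mid", "high")}
    for gene in genes:
        length = gene.length
        if length < n_bins:
            continue
        edges = gene.start + np.floor(length * np.arange(n_bins + 1) / n_bins).astype(int)
        sense_strand = gene.strand
        anti_strand = "-" if gene.strand == "+" else "+"
        sense = np.array([counts.window_sum(gene.contig, sense_strand, edges[j], edges[j + 1])
                          for j in range(n_bins)], dtype=float)
        anti = np.array([counts.window_sum(gene.contig, anti_strand, edges[j], edges[j + 1])
                         for j in range(n_bins)], dtype=float)
        if (sense > 0).sum() < min_signal_bins or (anti > 0).sum() < min_signal_bins:
            continue
        per_gene[group_of(gene)].append((sense.mean(), anti.mean()))

    rows = []
    for name in ("zero", "low", "mid", "high"):
        pairs = per_gene[name]
        if len(pairs) < 3:
            rows.append((name, len(pairs), np.nan, np.nan, np.nan))
            continue
        arr = np.array(pairs)
        diffs = arr[:, 0] - arr[:, 1]
        t, p = _paired_t(diffs)
        rows.append((name, len(pairs), float(diffs.mean()), t, p))
    return pd.DataFrame(rows, columns=["group", "n", "mean_diff", "t", "p"])


# ---------------------------------------------------------------------------
# Exon-intron boundary profiles
# ---------------------------------------------------------------------------

def _boundaries(gene: GeneModel) -> list[tuple[str, int]]:
    """(class, junction coordinate) pairs for internal exons, in gene
    orientation.  The junction coordinate is the plus-axis position of the
    first base on the 3' (downstream-in-gene) side of the junction."""
    out = []
    for s, e in gene.internal_exons():
        if gene.strand == "+":
            out.append(("intron_exon", s))   # intron ends, exon starts at s
            out.append(("exon_intron", e))   # exon ends at e-1, intron starts at e
        else:
            out.append(("intron_exon", e - 1))
            out.append(("exon_intron", s - 1))
    return out


def boundary_profile(
    table: SiteCoverageTable,
    gene_models: list[GeneModel],
    max_dist: int = 25,
) -> tuple[dict[tuple[str, str], ProfileMatrix], pd.DataFrame]:
    """Signal around internal-exon splice junctions, per class and strand.

    For each internal protein-coding exon two boundaries are scored
    (exon->intron and intron->exon).  Offsets run -max_dist..-1 on the 5'
    side of the junction and +1..+max_dist on the 3' side, in gene
    orientation; a site at distance ``max_dist + 1`` or farther is outside
    the window.  A boundary qualifies, per strand layer (sense/antisense to
    the gene), only when covered sites exist on both sides.  Side averages
    (mean count over covered sites) are compared across boundaries with a
    two-sided paired t-test per (class, strand).
    """
    counts = _StrandedCounts(table)
    offsets = [o for o in range(-max_dist, max_dist + 1) if o != 0]
    col_index = {o: i for i, o in enumerate(offsets)}

    matrices: dict[tuple[str, str], list[np.ndarray]] = {}
    sides: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for cls in ("exon_intron", "intron_exon"):
        for layer in ("sense", "antisense"):
            matrices[(cls, layer)] = []
            sides[(cls, layer)] = []

    for gene in gene_models:
        if not gene.is_protein_coding:
            continue
        sense_strand = gene.strand
        anti_strand = "-" if gene.strand == "+" else "+"
        sign = 1 if gene.strand == "+" else -1
        for cls, junction in _boundaries(gene):
            lo = min(junction - sign * max_dist, junction + sign * (max_dist - 1))
            hi = max(junction - sign * max_dist, junction + sign * (max_dist - 1)) + 1
            for layer, strand in (("sense", sense_strand), ("antisense", anti_strand)):
                pos, cnt = counts.window_counts(gene.contig, strand, lo, hi)
                if pos.size == 0:
                    continue
                # offset in gene orientation: +1 = junction base itself (3'
                # side of the cut), -1 = base immediately 5' of it
                raw = (pos - junction) * sign
                offs = np.where(raw >= 0, raw + 1, raw)
                keep = (np.abs(offs) <= max_dist) & (cnt > 0)
                offs, vals = offs[keep], cnt[keep]
                upstream = vals[offs < 0]
                downstream = vals[offs > 0]
                if upstream.size == 0 or downstream.size == 0:
                    continue
                row = np.full(len(offsets), np.nan)
                for o, v in zip(offs, vals):
                    row[col_index[int(o)]] = v
                matrices[(cls, layer)].append(row)
                # 5' side of an exon->intron junction is exonic; of an
                # intron->exon junction it is intronic
                if cls == "exon_intron":
                    exon_side, intron_side = upstream.mean(), downstream.mean()
                else:
                    exon_side, intron_side = downstream.mean(), upstream.mean()
                sides[(cls, layer)].append((float(exon_side), float(intron_side)))

    profiles = {
        key: ProfileMatrix(
            np.vstack(rows) if rows else np.empty((0, len(offsets))),
            columns=offsets, rows=list(range(len(rows))), label=f"{key[0]}/{key[1]}")
        for key, rows in matrices.items()
    }
    test_rows = []
    for (cls, layer), pairs in sides.items():
        if len(pairs) < 3:
            test_rows.append((cls, layer, len(pairs), np.nan, np.nan, np.nan))
            continue
        arr = np.array(pairs)
        diffs = arr[:, 0] - arr[:, 1]
        t, p = _paired_t(diffs)
        test_rows.append((cls, layer, len(pairs), float(diffs.mean()), t, p))
    tests = pd.DataFrame(
        test_rows, columns=["boundary_class", "strand", "n", "mean_diff", "t", "p"])
    return profiles, tests
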