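"""Calling hydroxymethylated non-CG (CH) cytosines.

CH calls demand more evidence than CG coverage because random priming can
mimic a low-coverage CH signal.  A site is called when (1) it has at least
one exact-start read in both technical replicates, (2) no CG dinucleotide
begins within k nt (default 7) downstream of it on its own strand — a CG
that close could be the true priming target — and (3) it is not recurrent
in unlabelled control libraries (present in fewer than two of them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .coverage import SiteCoverageTable
from .reference_sites import GenomeSequence, SiteRecord, has_downstream_cg


@dataclass
class ChCallSet:
    """Called CH sites with per-replicate counts, subclass (CA/CT/CC, the
    base following the C on the site strand) and context (CHG/CHH)."""

    calls: pd.DataFrame  # contig, pos, strand, subclass, context, count_rep1, count_rep2, count

    def __len__(self) -> int:
        return len(self.calls)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.calls.itertuples():
                fh.write(f"{row.contig}\t{row.pos}\t{row.pos + 1}\t"
                         f"{row.subclass}/{row.context}\t0\t{row.strand}\n")


def _subclass(genome: GenomeSequence, rec: SiteRecord) -> str:
    nxt = genome.strand_slice(rec.contig, rec.pos, 2, rec.strand)[1:]
    return "C" + nxt


def call_hmch(
    rep1: SiteCoverageTable,
    rep2: SiteCoverageTable,
    controls: Sequence[SiteCoverageTable] = (),
    genome: GenomeSequence | None = None,
    k: int = 7,
    control_filter: bool = True,
    coverage_summary: str = "mean",
) -> ChCallSet:
    """Apply the three CH-calling rules and return the called set.

    ``coverage_summary`` sets the reported per-site count: "mean" (default)
    or "sum" of the replicate counts.  ``control_filter=False`` keeps
    control-recurrent sites (flagged) instead of removing them.
    """
    if genome is None:
        raise ValueError("genome is required for the downstream-CG rule")
    if {r.key for r in rep1.records} != {r.key for r in rep2.records}:
        raise ValueError("replicate coverage tables come from different catalogs")
    if coverage_summary not in ("mean", "sum"):
        raise ValueError(f"unknown coverage summary {coverage_summary!r}")

    control_hits: dict[tuple, int] = {}
    for ctrl in controls:
        for key in ctrl.covered_keys():
            control_hits[key] = control_hits.get(key, 0) + 1

    rows = []
    for rec, c1 in zip(rep1.records, rep1.counts):
        if rec.context_class not in ("CHG", "CHH"):
            raise ValueError(f"non-CH site in CH coverage table: {rec}")
        c2 = rep2.get(rec)
        if c1 < 1 or c2 < 1:
            continue
        if has_downstream_cg(genome, rec, k):
            continue
        in_controls = control_hits.get(rec.key, 0) >= 2
        if control_filter and in_controls:
            continue
        count = (c1 + c2) / 2.0 if coverage_summary == "mean" else float(c1 + c2)
        rows.append((rec.contig, rec.pos, rec.strand, _subclass(genome, rec),
                     rec.context_class, int(c1), int(c2), count, in_controls))
    calls = pd.DataFrame(rows, columns=[
        "contig", "pos", "strand", "subclass", "context",
        "count_rep1", "count_rep2", "count", "control_overlap",
    ]).sort_values(["contig", "pos", "strand"], ignore_index=True)
    return ChCallSet(calls)


def ch_composition(calls: ChCallSet, genome: GenomeSequence | None = None) -> dict:
    """Subclass (CA/CT/CC) and context (CHG/CHH) proportions of a call set.

    Each partition's proportions sum to 1 exactly.
    """
    if len(calls) == 0:
        raise ValueError("empty call set")
    df = calls.calls
    n = len(df)
    sub = df["subclass"].value_counts()
    ctx = df["context"].value_counts()
    return {
        "n": n,
        "CA": sub.get("CA", 0) / n,
        "CT": sub.get("CT", 0) / n,
        "CC": sub.get("CC", 0) / n,
        "CHG": ctx.get("CHG", 0) / n,
        "CHH": ctx.get("CHH", 0) / n,
        "mean_coverage": float(df["count"].mean()),
    }
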