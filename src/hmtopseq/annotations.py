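"""Gene models and derived annotation feature classes.

Parses GTF gene models (gene/transcript/exon/CDS records; GENCODE-style
attributes) into 0-based half-open coordinates, derives introns, UTRs and
internal exons per transcript, and builds the annotation classes used by the
enrichment analyses: CGI shores (2-kb flanks), strand-aware promoters and
downstream regions (2 kb), intergenic space (>= 50 kb from any
protein-coding gene), and histone-mark-defined enhancer/promoter classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pyranges as pr


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]            # 0-based half-open, sorted genomically
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: list[Transcript]

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def length(self) -> int:
        return self.end - self.start

    def exons(self) -> list[tuple[int, int]]:
        """Union of exon intervals across transcripts."""
        return _merge([iv for t in self.transcripts for iv in t.exons])

    def introns(self) -> list[tuple[int, int]]:
        """Intra-gene space not covered by any exon."""
        merged = self.exons()
        out = []
        for (_, e1), (s2, _) in zip(merged, merged[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def internal_exons(self) -> list[tuple[int, int]]:
        """Exons that are neither first nor last of their transcript
        (union across transcripts)."""
        ivs = [iv for t in self.transcripts for iv in t.exons[1:-1] if len(t.exons) >= 3]
        return sorted(set(ivs))

    def utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) interval unions, derived from CDS where present."""
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        for t in self.transcripts:
            if not t.cds:
                continue
            cds_lo, cds_hi = t.cds[0][0], t.cds[-1][1]
            before = [(max(s, 0), min(e, cds_lo)) for s, e in t.exons if s < cds_lo]
            after = [(max(s, cds_hi), e) for s, e in t.exons if e > cds_hi]
            before = [(s, e) for s, e in before if e > s]
            after = [(s, e) for s, e in after if e > s]
            if self.strand == "+":
                utr5 += before
                utr3 += after
            else:
                utr5 += after
                utr3 += before
        return _merge(utr5), _merge(utr3)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gene_models(gtf_path) -> list[GeneModel]:
    """Load gene models from a GTF into :class:`GeneModel` records.

    GTF's 1-based closed coordinates become 0-based half-open.  Exons whose
    transcript was never declared are fatal.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        transcripts[tid] = Transcript(tid, [])
        tx_gene[tid] = t.attributes["gene_id"][0]
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        if tid not in transcripts:
            raise ValueError(f"orphan exon: transcript {tid!r} not declared")
        transcripts[tid].exons.append((ex.start - 1, ex.end))
    for cds in db.features_of_type("CDS"):
        tid = cds.attributes["transcript_id"][0]
        if tid not in transcripts:
            raise ValueError(f"orphan CDS: transcript {tid!r} not declared")
        transcripts[tid].cds.append((cds.start - 1, cds.end))

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        biotype = (g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or ["unknown"])[0]
        txs = [Transcript(t.transcript_id, sorted(t.exons), sorted(t.cds))
               for t in transcripts.values() if tx_gene[t.transcript_id] == gid]
        for t in txs:
            if not t.exons:
                raise ValueError(f"transcript {t.transcript_id!r} has no exons")
        genes.append(GeneModel(
            gene_id=gid, contig=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end, biotype=biotype, transcripts=txs,
        ))
    return genes


# ---------------------------------------------------------------------------
# Feature sets
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Label -> half-open interval table (contig, start, end)."""

    features: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __getitem__(self, label: str) -> pd.DataFrame:
        return self.features[label]

    def __contains__(self, label: str) -> bool:
        return label in self.features

    def labels(self) -> list[str]:
        return list(self.features)

    def add(self, label: str, intervals: pd.DataFrame) -> None:
        self.features[label] = intervals.reset_index(drop=True)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for label, df in self.features.items():
                for row in df.itertuples():
                    fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{label}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3+ reader; extra columns beyond contig/start/end/name/score/strand
    are ignored."""
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def _to_pr(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(pd.DataFrame({
        "Chromosome": df["contig"], "Start": df["start"], "End": df["end"],
    }))


def _from_pr(ranges: pr.PyRanges) -> pd.DataFrame:
    if len(ranges) == 0:
        return pd.DataFrame(columns=["contig", "start", "end"])
    df = ranges.df
    out = pd.DataFrame({
        "contig": df["Chromosome"].astype(str), "start": df["Start"], "end": df["End"],
    })
    return out.sort_values(["contig", "start", "end"], ignore_index=True)


def _clamp(df: pd.DataFrame, lengths: dict[str, int] | None) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].clip(lower=0)
    if lengths:
        df["end"] = [min(e, lengths.get(c, e)) for c, e in zip(df["contig"], df["end"])]
    df = df[df["end"] > df["start"]]
    return df.reset_index(drop=True)


def derive_features(
    genes: list[GeneModel],
    cgi: pd.DataFrame | None = None,
    repeats: pd.DataFrame | None = None,
    histone_peaks: dict[str, pd.DataFrame] | None = None,
    lengths: dict[str, int] | None = None,
    flank: int = 2_000,
    intergenic_dist: int = 50_000,
) -> FeatureSet:
    """Build the annotation classes driving the enrichment analyses.

    * shores: 2-kb flanks on each side of a CGI, CGI bodies excluded;
    * promoter / downstream: 2-kb strand-aware regions off the gene TSS/TES;
    * intergenic: >= ``intergenic_dist`` from any protein-coding gene span
      (requires contig ``lengths``);
    * poised_enhancer: H3K4me1 minus H3K27ac; active_enhancer: H3K4me1 and
      H3K27ac; active_promoter: promoter and H3K9ac; nonactive_promoter:
      promoter minus H3K9ac.

    Classes whose required inputs are absent are simply not produced, except
    when explicitly requested through the presence of a partial histone set
    (a missing companion track raises, naming the class).
    """
    fs = FeatureSet()
    histone_peaks = histone_peaks or {}

    if cgi is not None:
        fs.add("cgi", cgi[["contig", "start", "end"]])
        left = cgi.assign(start=cgi["start"] - flank, end=cgi["start"])
        right = cgi.assign(start=cgi["end"], end=cgi["end"] + flank)
        shores = _clamp(pd.concat([left, right])[["contig", "start", "end"]], lengths)
        shores = _from_pr(_to_pr(shores).subtract(_to_pr(cgi)))
        fs.add("cgi_shore", shores)

    if repeats is not None:
        fs.add("repeat", repeats[["contig", "start", "end"]])

    if genes:
        prom_rows, down_rows = [], []
        for g in genes:
            if g.strand == "+":
                prom_rows.append((g.contig, g.start - flank, g.start))
                down_rows.append((g.contig, g.end, g.end + flank))
            else:
                prom_rows.append((g.contig, g.end, g.end + flank))
                down_rows.append((g.contig, g.start - flank, g.start))
        promoters = _clamp(pd.DataFrame(prom_rows, columns=["contig", "start", "end"]), lengths)
        fs.add("promoter", promoters)
        fs.add("downstream", _clamp(pd.DataFrame(down_rows, columns=["contig", "start", "end"]), lengths))

        exons = [(g.contig, s, e) for g in genes for s, e in g.exons()]
        introns = [(g.contig, s, e) for g in genes for s, e in g.introns()]
        fs.add("exon", pd.DataFrame(exons, columns=["contig", "start", "end"]))
        fs.add("intron", pd.DataFrame(introns, columns=["contig", "start", "end"]))
        utr5_rows, utr3_rows = [], []
        for g in genes:
            u5, u3 = g.utrs()
            utr5_rows += [(g.contig, s, e) for s, e in u5]
            utr3_rows += [(g.contig, s, e) for s, e in u3]
        fs.add("utr5", pd.DataFrame(utr5_rows, columns=["contig", "start", "end"]))
        fs.add("utr3", pd.DataFrame(utr3_rows, columns=["contig", "start", "end"]))

        if lengths:
            coding = [(g.contig, g.start - intergenic_dist, g.end + intergenic_dist)
                      for g in genes if g.is_protein_coding]
            buffered = _clamp(pd.DataFrame(coding, columns=["contig", "start", "end"]), lengths)
            whole = pd.DataFrame(
                [(c, 0, L) for c, L in lengths.items()], columns=["contig", "start", "end"])
            if len(buffered):
                intergenic = _from_pr(_to_pr(whole).subtract(_to_pr(buffered)))
            else:
                intergenic = whole
            fs.add("intergenic", intergenic)

    if "H3K4me1" in histone_peaks:
        if "H3K27ac" not in histone_peaks:
            raise ValueError("enhancer classes need both H3K4me1 and H3K27ac tracks")
        k4 = _to_pr(histone_peaks["H3K4me1"])
        k27 = _to_pr(histone_peaks["H3K27ac"])
        fs.add("poised_enhancer", _from_pr(k4.subtract(k27)))
        fs.add("active_enhancer", _from_pr(k4.intersect(k27)))

    if "H3K9ac" in histone_peaks:
        if "promoter" not in fs:
            raise ValueError("active/nonactive promoter classes need gene models")
        prom = _to_pr(fs["promoter"])
        k9 = _to_pr(histone_peaks["H3K9ac"])
        fs.add("active_promoter", _from_pr(prom.intersect(k9)))
        fs.add("nonactive_promoter", _from_pr(prom.subtract(k9)))

    return fs
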