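import numpy as np
import pytest

from hmtopseq import GenomeSequence, make_random_genome


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    """10-kb random genome used by scan-oracle tests."""
    return make_random_genome(10_000, seed=42, name="c1")


@pytest.fixture()
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"c1": "ACGTGCGCATTACGCGAACCGT", "c2": "TTCGAAGCGCTT"})


def write_gtf(path, genes):
    """Write a toy GTF.

    ``genes`` is a list of dicts with keys: gene_id, contig, strand,
    biotype, transcripts -> list of (transcript_id, exons, cds) where exons
    and cds are lists of 0-based half-open intervals.
    """
    lines = []
    for g in genes:
        tx_spans = [t[1] for t in g["transcripts"]]
        lo = min(s for exons in tx_spans for s, _ in exons)
        hi = max(e for exons in tx_spans for _, e in exons)
        attrs = f'gene_id "{g["gene_id"]}"; gene_type "{g.get("biotype", "protein_coding")}";'
        lines.append(f'{g["contig"]}\ttest\tgene\t{lo + 1}\t{hi}\t.\t{g["strand"]}\t.\t{attrs}')
        for tid, exons, cds in g["transcripts"]:
            tlo = min(s for s, _ in exons)
            thi = max(e for _, e in exons)
            tattrs = attrs + f' transcript_id "{tid}";'
            lines.append(
                f'{g["contig"]}\ttest\ttranscript\t{tlo + 1}\t{thi}\t.\t{g["strand"]}\t.\t{tattrs}')
            for s, e in exons:
                lines.append(
                    f'{g["contig"]}\ttest\texon\t{s + 1}\t{e}\t.\t{g["strand"]}\t.\t{tattrs}')
            for s, e in cds or []:
                lines.append(
                    f'{g["contig"]}\ttest\tCDS\t{s + 1}\t{e}\t.\t{g["strand"]}\t0\t{tattrs}')
    path.write_text("\n".join(lines) + "\n")
    return path
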