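"""Regression, enrichment, metagene, strand-bias and boundary statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from hmtopseq import (
    FeatureSet,
    GeneModel,
    SiteCoverageTable,
    SiteRecord,
    Transcript,
    boundary_profile,
    feature_enrichment,
    fit_titration,
    metagene_profile,
    signal_groups,
    strand_bias,
)
from hmtopseq.reference_sites import SiteCatalog


# ---------------------------------------------------------------------------
# fit_titration
# ---------------------------------------------------------------------------

def test_recovers_exact_quadratic_generator():
    """Data generated from Y = 99.5 + 15.7X - 0.240X^2 is refit to machine
    precision with R^2 = 1."""
    x = np.array([2.5, 5.0, 10.0, 20.0, 40.0])
    y = 99.5 + 15.7 * x - 0.240 * x**2
    fit = fit_titration(x, y)
    assert fit.b0 == pytest.approx(99.5, abs=1e-8)
    assert fit.b1 == pytest.approx(15.7, abs=1e-8)
    assert fit.b2 == pytest.approx(-0.240, abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.predict([10.0])[0] == pytest.approx(99.5 + 157 - 24)


def test_constant_response_gives_zero_slope_and_r2():
    fit = fit_titration([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
    assert (fit.b1, fit.b2, fit.r_squared) == (0.0, 0.0, 0.0)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        x = rng.uniform(0, 50, size=rng.integers(5, 30))
        y = rng.normal(size=len(x)) + 0.5 * x
        fit = fit_titration(x, y)
        X = np.column_stack([np.ones_like(x), x, x * x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose([fit.b0, fit.b1, fit.b2], beta, atol=1e-8)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)
        n = len(x)
        assert fit.adj_r_squared == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 3), abs=1e-8)


def test_collinear_or_tiny_designs_are_errors():
    with pytest.raises(ValueError, match="at least 4"):
        fit_titration([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="distinct"):
        fit_titration([1, 1, 2, 2], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# signal groups
# ---------------------------------------------------------------------------

def _table_with_counts(counts):
    recs = tuple(SiteRecord("c", 10 * i, "+", "CG") for i in range(len(counts)))
    return SiteCoverageTable(recs, np.asarray(counts), {"c": 10 * len(counts) + 10})


def test_percentile_bands_on_distinct_counts():
    groups = signal_groups(_table_with_counts([1, 2, 3, 4, 5, 6, 7, 8, 9, 10]))
    by_count = {name: sorted(r.pos // 10 + 1 for r in members)
                for name, members in groups.groups.items()}
    assert by_count == {"low": [1, 2], "mid": [5, 6], "high": [9, 10]}
    assert not groups.degenerate


def test_methods_scheme_narrows_middle_band():
    groups = signal_groups(_table_with_counts(list(range(1, 21))), scheme="methods")
    assert groups.sizes == {"low": 4, "mid": 2, "high": 4}


def test_all_equal_counts_flagged_degenerate():
    groups = signal_groups(_table_with_counts([3] * 10))
    assert groups.degenerate


def test_groups_match_sortbased_oracle():
    rng = np.random.default_rng(29)
    counts = rng.poisson(5, size=200) + 1
    groups = signal_groups(_table_with_counts(counts))
    order = np.argsort(counts, kind="stable")
    n = len(counts)
    expect_low = {int(order[i]) for i in range(int(0.2 * n))}
    got_low = {r.pos // 10 for r in groups.groups["low"]}
    assert got_low == expect_low


# ---------------------------------------------------------------------------
# feature enrichment
# ---------------------------------------------------------------------------

def _partition_from_membership(in_group, in_other):
    from hmtopseq.stats_profiles import SignalGroups
    return SignalGroups({"high": in_group, "rest": in_other})


def test_odds_ratio_cross_product_example():
    """10 group sites with 8 in the feature vs 90 others with 20 inside
    gives OR = (8*70)/(2*20) = 14."""
    group = [SiteRecord("c", i, "+", "CG") for i in range(10)]
    other = [SiteRecord("c", 1_000 + i, "+", "CG") for i in range(90)]
    feat_iv = [(0, 8), (1_000, 1_020)]
    fs = FeatureSet({"f": pd.DataFrame(
        [("c", s, e) for s, e in feat_iv], columns=["contig", "start", "end"])})
    results = feature_enrichment(_partition_from_membership(group, other), fs)
    high = next(r for r in results if r.group == "high")
    assert (high.a, high.b, high.c, high.d) == (8, 2, 20, 70)
    assert high.odds_ratio == pytest.approx(14.0)


def test_fisher_p_matches_hypergeometric_enumeration():
    """Two-sided exact p equals full enumeration of tables with the same
    margins (n <= 50)."""
    rng = np.random.default_rng(31)
    for _ in range(10):
        n = int(rng.integers(10, 51))
        n_group = int(rng.integers(2, n - 1))
        n_feat = int(rng.integers(1, n))
        pos = rng.permutation(n)
        group = [SiteRecord("c", int(2 * p), "+", "CG") for p in pos[:n_group]]
        other = [SiteRecord("c", int(2 * p), "+", "CG") for p in pos[n_group:]]
        feat = pd.DataFrame([("c", 2 * k, 2 * k + 1) for k in range(n_feat)],
                            columns=["contig", "start", "end"])
        fs = FeatureSet({"f": feat})
        res = next(r for r in feature_enrichment(_partition_from_membership(group, other), fs)
                   if r.group == "high")
        # enumeration oracle over a with fixed margins
        row1, col1 = res.a + res.b, res.a + res.c
        probs = []
        for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            probs.append(math.comb(col1, a) * math.comb(n - col1, row1 - a) / math.comb(n, row1))
        p_obs = probs[res.a - max(0, row1 + col1 - n)]
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(expected, rel=1e-6)


def test_zero_cell_gets_haldane_estimate():
    group = [SiteRecord("c", i, "+", "CG") for i in range(5)]
    other = [SiteRecord("c", 1_000 + i, "+", "CG") for i in range(5)]
    fs = FeatureSet({"f": pd.DataFrame([("c", 0, 10)], columns=["contig", "start", "end"])})
    res = next(r for r in feature_enrichment(_partition_from_membership(group, other), fs)
               if r.group == "high")
    assert res.degenerate and np.isfinite(res.odds_ratio) and res.odds_ratio > 0


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def _dense_cg_setup(n=4_000):
    """'ACGT' repeats: a CG locus every 4 bp on both strands."""
    from hmtopseq import GenomeSequence, find_cg_sites
    genome = GenomeSequence({"c": "ACGT" * n})
    catalog = find_cg_sites(genome)
    return genome, catalog


def test_uniform_coverage_gives_flat_profile():
    genome, catalog = _dense_cg_setup()
    c = 3
    table = SiteCoverageTable(tuple(catalog.records),
                              np.full(len(catalog), c), genome.lengths)
    gene = GeneModel("g", "c", "+", 3_000, 6_000, "protein_coding",
                     [Transcript("t", [(3_000, 4_000), (5_000, 6_000)], [(3_200, 3_900)])])
    profiles = metagene_profile(table, [gene], catalog)
    for elem in ("upstream", "exon", "intron", "downstream"):
        means = profiles[elem].column_means()
        np.testing.assert_allclose(means, c, err_msg=elem)


def test_manual_binning_oracle():
    genome, catalog = _dense_cg_setup()
    counts = np.zeros(len(catalog), int)
    table = SiteCoverageTable(tuple(catalog.records), counts, genome.lengths)
    # gene exon [1000, 2000): bin width 100; place 5 reads on the site at
    # 1001 (bin 0) and 7 at 1505 (bin 5)
    idx = {r.key: i for i, r in enumerate(table.records)}
    counts[idx[("c", 1001, "+")]] = 5
    counts[idx[("c", 1506, "-")]] = 7
    table = SiteCoverageTable(tuple(catalog.records), counts, genome.lengths)
    gene = GeneModel("g", "c", "+", 1_000, 2_000, "protein_coding",
                     [Transcript("t", [(1_000, 2_000)])])
    prof = metagene_profile(table, [gene], catalog)["exon"]
    (row,) = prof.values
    # each 100-bp bin holds 50 per-strand sites (25 loci x 2 strands)
    assert row[0] == pytest.approx(5 / 50)
    assert row[5] == pytest.approx(7 / 50)
    assert np.nansum(row) == pytest.approx(5 / 50 + 7 / 50)


def test_minus_strand_gene_traversed_5prime_to_3prime():
    genome, catalog = _dense_cg_setup()
    counts = np.zeros(len(catalog), int)
    idx = {r.key: i for i, r in enumerate(catalog.records)}
    counts[idx[("c", 1001, "+")]] = 9  # genomically first bin
    table = SiteCoverageTable(tuple(catalog.records), counts, genome.lengths)
    minus = GeneModel("g", "c", "-", 1_000, 2_000, "protein_coding",
                      [Transcript("t", [(1_000, 2_000)])])
    prof = metagene_profile(table, [minus], catalog)["exon"]
    (row,) = prof.values
    assert row[9] > 0 and row[0] == 0  # 5' of a minus gene is the high coordinate


def test_profile_scales_linearly_with_counts():
    genome, catalog = _dense_cg_setup()
    rng = np.random.default_rng(37)
    counts = rng.poisson(2, len(catalog))
    gene = GeneModel("g", "c", "+", 2_000, 5_000, "protein_coding",
                     [Transcript("t", [(2_000, 5_000)])])
    t1 = SiteCoverageTable(tuple(catalog.records), counts, genome.lengths)
    t3 = SiteCoverageTable(tuple(catalog.records), 3 * counts, genome.lengths)
    p1 = metagene_profile(t1, [gene], catalog)["exon"].values
    p3 = metagene_profile(t3, [gene], catalog)["exon"].values
    np.testing.assert_allclose(p3, 3 * p1, equal_nan=True)


# ---------------------------------------------------------------------------
# strand bias
# ---------------------------------------------------------------------------

def _strand_bias_setup(n_genes=24, gene_len=1_200, lam=1.0, inject=None, seed=0):
    """Genes tiled on one contig; CG sites every 10 bp on both strands.

    ``inject`` maps expression-group name -> sense-strand count boost.
    Returns (table, genes, expression).
    """
    rng = np.random.default_rng(seed)
    genes, records, counts, expression = [], [], [], {}
    group_names = ["zero", "low", "mid", "high"]
    for i in range(n_genes):
        start = i * (gene_len + 400) + 200
        gid = f"g{i}"
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gid, "c", strand, start, start + gene_len,
                               "protein_coding",
                               [Transcript(f"t{i}", [(start, start + gene_len)])]))
        grp = group_names[i % 4]
        expression[gid] = {"zero": 0.0, "low": 1.0, "mid": 5.0, "high": 25.0}[grp]
        boost = (inject or {}).get(grp, 0)
        for j in range(0, gene_len, 10):
            for s in ("+", "-"):
                pos = start + j + (0 if s == "+" else 1)
                sense = s == strand
                records.append(SiteRecord("c", pos, s, "CG"))
                counts.append(rng.poisson(lam + (boost if sense else 0)))
    table = SiteCoverageTable(tuple(records), np.array(counts),
                              {"c": n_genes * (gene_len + 400) + 1_000})
    return table, genes, expression


def test_symmetric_coverage_has_small_mean_difference():
    table, genes, expr = _strand_bias_setup(seed=1)
    out = strand_bias(table, genes, expr)
    assert set(out["group"]) == {"zero", "low", "mid", "high"}
    assert (out["n"] >= 3).all()
    assert out["mean_diff"].abs().max() < 0.2
    assert ((out["p"] > 0) & (out["p"] <= 1)).all()


def test_injected_sense_excess_detected_only_in_target_group():
    table, genes, expr = _strand_bias_setup(inject={"high": 2.0}, seed=2)
    out = strand_bias(table, genes, expr).set_index("group")
    assert out.loc["high", "p"] < 1e-4
    assert out.loc["high", "mean_diff"] > 1.0
    for grp in ("zero", "low", "mid"):
        assert out.loc[grp, "p"] > 0.01


def test_all_zero_differences_report_p_one():
    table, genes, expr = _strand_bias_setup(lam=0, seed=3)
    # give every site the same constant count: strands exactly balance
    table = table.with_counts(np.full(len(table.records), 2))
    out = strand_bias(table, genes, expr).set_index("group")
    assert (out["mean_diff"] == 0).all()
    assert (out["p"] == 1.0).all()


def test_groups_with_too_few_genes_are_missing():
    table, genes, expr = _strand_bias_setup(n_genes=4, seed=4)
    out = strand_bias(table, genes, expr).set_index("group")
    assert out["p"].isna().all()  # 1 gene per group


# ---------------------------------------------------------------------------
# boundary profile
# ---------------------------------------------------------------------------

def _single_gene_with_internal_exon():
    gene = GeneModel("g", "c", "+", 100, 1_000, "protein_coding",
                     [Transcript("t", [(100, 300), (400, 600), (700, 1_000)])])
    return gene


def _boundary_table(site_counts):
    records = tuple(SiteRecord("c", pos, strand, "CG")
                    for (pos, strand) in site_counts)
    counts = np.array(list(site_counts.values()))
    return SiteCoverageTable(records, counts, {"c": 2_000})


def test_manual_boundary_oracle():
    """Hand-placed counts around the internal exon [400, 600) of a plus
    gene: junctions at 400 (intron->exon) and 600 (exon->intron)."""
    gene = _single_gene_with_internal_exon()
    table = _boundary_table({
        (595, "+"): 4,   # offset -5 exonic side of the 600 junction
        (604, "+"): 2,   # offset +5 intronic side
        (395, "+"): 6,   # offset -5 intronic side of the 400 junction
        (402, "+"): 8,   # offset +3 exonic side
    })
    profiles, tests = boundary_profile(table, [gene])
    ei = profiles[("exon_intron", "sense")]
    (row_ei,) = ei.values
    cols = {o: i for i, o in enumerate(ei.columns)}
    assert row_ei[cols[-5]] == 4 and row_ei[cols[5]] == 2
    ie = profiles[("intron_exon", "sense")]
    (row_ie,) = ie.values
    assert row_ie[cols[-5]] == 6 and row_ie[cols[3]] == 8
    t = tests.set_index(["boundary_class", "strand"])
    assert t.loc[("exon_intron", "sense"), "n"] == 1
    # antisense layer has no covered sites at all
    assert t.loc[("exon_intron", "antisense"), "n"] == 0


def test_distance_26_site_is_excluded():
    gene = _single_gene_with_internal_exon()
    # 600 junction: offsets +25 is pos 624, +26 is pos 625
    t_in = _boundary_table({(575, "+"): 1, (624, "+"): 1})
    profiles, _ = boundary_profile(t_in, [gene])
    assert len(profiles[("exon_intron", "sense")].values) == 1
    t_out = _boundary_table({(575, "+"): 1, (625, "+"): 1})
    profiles2, _ = boundary_profile(t_out, [gene])
    assert len(profiles2[("exon_intron", "sense")].values) == 0  # one side empty


def test_boundaries_need_cover_on_both_sides():
    gene = _single_gene_with_internal_exon()
    table = _boundary_table({(595, "+"): 3})  # exonic side only
    profiles, tests = boundary_profile(table, [gene])
    assert all(len(m.values) == 0 for m in profiles.values())
    assert tests["p"].isna().all()


def test_minus_strand_gene_orientation():
    """For a minus-strand gene the exon->intron junction of internal exon
    [400, 600) sits at the low-coordinate edge."""
    gene = GeneModel("g", "c", "-", 100, 1_000, "protein_coding",
                     [Transcript("t", [(100, 300), (400, 600), (700, 1_000)])])
    # site 5 nt into the exon (gene orientation: upstream of the 399 junction)
    table = _boundary_table({(404, "-"): 4, (395, "-"): 2})
    profiles, _ = boundary_profile(table, [gene])
    ei = profiles[("exon_intron", "sense")]
    (row,) = ei.values
    cols = {o: i for i, o in enumerate(ei.columns)}
    assert row[cols[-5]] == 4 and row[cols[5]] == 2
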