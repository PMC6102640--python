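"""Fisher enrichment, BH adjustment, GWAS join and SNP-density comparison."""

import numpy as np
import pandas as pd
import pytest
from oracle_utils import student_t_equal_var
from scipy.stats import fisher_exact
from scipy.special import comb

from ervscan.enrichment import (
    AnnotationSet,
    fisher_enrichment,
    fisher_exact_p,
    generic_set_enrichment,
    gwas_lookup,
    per_site_tissue_enrichment,
    pooled_enrichment,
    snp_density,
)
from ervscan.errors import InputError


def _annotation(members, universe, name="ann"):
    return AnnotationSet(name, set(members), set(universe))


# -------------------------------------------------------------- exactness


def test_balanced_table_is_null():
    universe = [f"s{i}" for i in range(20)]
    ann = _annotation(universe[:5] + universe[10:15], universe)
    res = fisher_enrichment(set(universe[:10]), ann)
    assert (res.a, res.b, res.c, res.d) == (5, 5, 5, 5)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_perfectly_concordant_table():
    """(10,0,0,10): two-sided p = 2 / C(20,10)."""
    p = fisher_exact_p(10, 0, 0, 10)
    assert p == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-12)


def test_agrees_with_scipy_on_exhaustive_small_tables():
    """All 2x2 tables with grand total <= 25 match an independent
    implementation exactly."""
    for n in range(0, 26):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    ours = fisher_exact_p(a, b, c, d)
                    ref = fisher_exact([[a, b], [c, d]])[1]
                    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-14)


def test_p_invariant_under_table_transposition(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 25, size=4)
        assert fisher_exact_p(a, b, c, d) == pytest.approx(
            fisher_exact_p(a, c, b, d), rel=1e-12)


def test_zero_cell_odds_ratios_flagged():
    universe = [f"s{i}" for i in range(40)]
    ann = _annotation(universe[:20], universe)
    res = fisher_enrichment(set(universe[:20]), ann)   # b = c = 0
    assert np.isinf(res.odds_ratio) and not res.or_defined
    res0 = fisher_enrichment(set(universe[20:25]), ann)  # a = 0
    assert res0.odds_ratio == 0.0 and not res0.or_defined


def test_query_outside_universe_rejected():
    ann = _annotation(["a"], ["a", "b"])
    with pytest.raises(InputError):
        fisher_enrichment({"zzz"}, ann)


def test_null_type_one_error_calibrated(rng):
    """Uniform random query sets: Fisher p < 0.05 within binomial 99% CI."""
    universe = np.arange(10_000)
    annotated = set(map(str, rng.choice(universe, 1_000, replace=False)))
    ann = _annotation(annotated, set(map(str, universe)))
    reps, hits = 2_000, 0
    for _ in range(reps):
        q = set(map(str, rng.choice(universe, 200, replace=False)))
        if fisher_enrichment(q, ann).p_value < 0.05:
            hits += 1
    ci = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits / reps - 0.05) < ci + 0.005


def test_planted_enrichment_has_power(rng):
    """5x over-representation, |q|=200, |ann|=1000, |U|=10000: p < 1e-6."""
    universe = [f"s{i}" for i in range(10_000)]
    hits = 0
    reps = 60
    for _ in range(reps):
        ann_ids = rng.choice(10_000, 1_000, replace=False)
        ann = _annotation({f"s{i}" for i in ann_ids}, universe)
        p_in = 5 * 0.1 / (5 * 0.1 + 0.9)
        q = set()
        in_ann = list(ann.members)
        out_ann = list(set(universe) - ann.members)
        n_in = rng.binomial(200, p_in)
        q |= set(rng.choice(in_ann, n_in, replace=False))
        q |= set(rng.choice(out_ann, 200 - n_in, replace=False))
        if fisher_enrichment(q, ann).p_value < 1e-6:
            hits += 1
    assert hits / reps >= 0.95


# ----------------------------------------------------------- composition


def test_per_site_matrix_equals_individual_tests():
    universe = [f"s{i}" for i in range(100)]
    anns = [_annotation(universe[:30], universe, "t1"),
            _annotation(universe[50:70], universe, "t2")]
    sets = {"siteA": set(universe[:10]), "siteB": set(universe[20:40])}
    long, matrix = per_site_tissue_enrichment(sets, anns)
    assert len(long) == 4
    for row in long.itertuples():
        solo = fisher_enrichment(sets[row.query],
                                 next(a for a in anns if a.name == row.annotation))
        assert row.p_value == pytest.approx(solo.p_value, rel=1e-12)
        assert matrix.loc[row.query, row.annotation] == pytest.approx(
            -np.log10(solo.p_value), rel=1e-9)


def test_empty_hisnp_set_row_flagged():
    universe = [f"s{i}" for i in range(50)]
    anns = [_annotation(universe[:10], universe, "t1")]
    long, _ = per_site_tissue_enrichment({"siteA": set()}, anns)
    assert not long["or_defined"].iloc[0] and np.isnan(long["p_value"].iloc[0])


def test_annotation_equal_to_universe_is_degenerate():
    universe = [f"s{i}" for i in range(30)]
    anns = [_annotation(universe, universe, "all")]
    long, _ = per_site_tissue_enrichment({"siteA": set(universe[:5])}, anns)
    assert not long["or_defined"].iloc[0]  # b = d = 0


def test_pooled_union_counts_duplicates_once():
    universe = [f"s{i}" for i in range(100)]
    ann = _annotation(universe[:40], universe)
    sets = {"A": set(universe[:10]), "B": set(universe[5:15])}
    res = pooled_enrichment(sets, ann)
    assert res.a + res.b == 15  # union size, not 20
    solo = fisher_enrichment(set(universe[:15]), ann)
    assert res.p_value == pytest.approx(solo.p_value, rel=1e-12)


def test_planted_cell_has_minimum_p(rng):
    """A site whose hiSNPs are 5x over-represented in one tissue yields the
    matrix minimum p in that cell in >= 95% of simulations."""
    universe = [f"s{i}" for i in range(2_000)]
    wins = 0
    reps = 200
    for _ in range(reps):
        anns = []
        for t in range(3):
            ids = rng.choice(2_000, 200, replace=False)
            anns.append(_annotation({f"s{i}" for i in ids}, universe, f"t{t}"))
        planted = anns[0].members
        q_in = rng.choice(sorted(planted), 40, replace=False)
        q_out = rng.choice(sorted(set(universe) - planted), 40, replace=False)
        sets = {
            "hot": set(q_in) | set(q_out),
            "cold": {f"s{i}" for i in rng.choice(2_000, 80, replace=False)},
        }
        long, _ = per_site_tissue_enrichment(sets, anns)
        best = long.loc[long["p_value"].idxmin()]
        if best["query"] == "hot" and best["annotation"] == "t0":
            wins += 1
    assert wins / reps >= 0.95


# --------------------------------------------------------------- BH / FDR


def test_bh_single_set_q_equals_p():
    universe = [f"s{i}" for i in range(100)]
    df = generic_set_enrichment(set(universe[:20]),
                                [_annotation(universe[:30], universe, "t")])
    assert df["fdr_q"].iloc[0] == pytest.approx(df["p_value"].iloc[0])


def test_bh_on_tied_p_values():
    from ervscan.enrichment import EnrichmentResult, apply_bh

    results = [EnrichmentResult("q", f"a{i}", 1, 1, 1, 1, 1.0, 0.01)
               for i in range(7)]
    apply_bh(results)
    assert all(r.fdr_q == pytest.approx(0.01) for r in results)


def test_bh_q_monotone_and_bounded(rng):
    from ervscan.enrichment import EnrichmentResult, apply_bh

    results = [EnrichmentResult("q", f"a{i}", 1, 1, 1, 1, 1.0,
                                float(rng.random())) for i in range(50)]
    apply_bh(results)
    df = pd.DataFrame([(r.p_value, r.fdr_q) for r in results],
                      columns=["p", "q"]).sort_values("p")
    assert (df["q"].diff().dropna() >= -1e-12).all()
    assert (df["q"] <= 1.0 + 1e-12).all()
    assert (df["q"] >= df["p"] - 1e-12).all()


def test_null_fdr_rarely_significant(rng):
    universe = [f"s{i}" for i in range(2_000)]
    n_sig = 0
    reps = 200
    for _ in range(reps):
        anns = [
            _annotation({f"s{i}" for i in rng.choice(2_000, 200, replace=False)},
                        universe, f"t{t}") for t in range(5)
        ]
        q = {f"s{i}" for i in rng.choice(2_000, 100, replace=False)}
        df = generic_set_enrichment(q, anns)
        n_sig += int(df["significant"].sum() > 0)
    assert n_sig / reps <= 0.08


# ------------------------------------------------------------- GWAS join


def test_gwas_join_counts_snps_and_traits():
    catalog = pd.DataFrame({
        "rsid": ["rs1", "rs2", "rs3", "rs4", "badid"],
        "trait": ["height", "height", "bmi", "asthma", "x"],
        "p": [1e-9] * 5,
    })
    sets = {"siteA": {"rs1", "rs2", "rs3"}, "siteB": {"rs999"}}
    with pytest.warns(UserWarning, match="malformed"):
        joined, counts = gwas_lookup(sets, catalog)
    row = counts.set_index("site_id").loc["siteA"]
    assert (row["n_snps"], row["n_traits"]) == (3, 2)
    assert "siteB" not in set(joined["site_id"])


def test_gwas_join_no_overlap_is_empty():
    catalog = pd.DataFrame({"rsid": ["rs1"], "trait": ["height"]})
    joined, counts = gwas_lookup({"s": {"rs2"}}, catalog)
    assert joined.empty and counts.empty


# ------------------------------------------------------------ SNP density


def test_density_counts_match_linear_scan(rng):
    positions = {"chr1": np.sort(rng.integers(0, 3_000_000, size=4_000))}
    sites = pd.DataFrame({
        "site_id": [f"x{i}" for i in range(6)],
        "chrom": "chr1",
        "pos": rng.integers(600_000, 2_400_000, size=6),
        "group": ["with_hisnps"] * 3 + ["common_without"] * 3,
    })
    report = snp_density(sites, positions)
    for row in report.counts.itertuples():
        for w in (1_000_000, 500_000, 100_000):
            brute = int(np.sum((positions["chr1"] >= row.pos - w // 2)
                               & (positions["chr1"] < row.pos + w // 2)))
            assert getattr(row, f"count_{w}") == brute
    # nested windows are monotone
    assert (report.counts["count_100000"] <= report.counts["count_500000"]).all()
    assert (report.counts["count_500000"] <= report.counts["count_1000000"]).all()


def test_density_t_test_matches_textbook_formula(rng):
    positions = {"chr1": np.sort(rng.integers(0, 5_000_000, size=6_000))}
    sites = pd.DataFrame({
        "site_id": [f"x{i}" for i in range(12)],
        "chrom": "chr1",
        "pos": rng.integers(600_000, 4_400_000, size=12),
        "group": ["with_hisnps"] * 6 + ["common_without"] * 6,
    })
    report = snp_density(sites, positions)
    row = report.summary[report.summary["window"] == 1_000_000].iloc[0]
    g1 = report.counts[report.counts["group"] == "common_without"]["count_1000000"]
    g2 = report.counts[report.counts["group"] == "with_hisnps"]["count_1000000"]
    t, p = student_t_equal_var(g1.to_numpy(float), g2.to_numpy(float))
    assert row["t"] == pytest.approx(t, abs=1e-10)
    assert row["p"] == pytest.approx(p, abs=1e-10)


def test_site_with_no_nearby_snps_counts_zero():
    positions = {"chr1": np.array([10, 20])}
    sites = pd.DataFrame({"site_id": ["a"], "chrom": ["chr2"], "pos": [1_000_000],
                          "group": ["with_hisnps"]})
    report = snp_density(sites, positions)
    assert (report.counts[["count_1000000", "count_500000", "count_100000"]]
            .to_numpy() == 0).all()
    assert np.isnan(report.summary["t"]).all()  # single tiny group: flagged
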