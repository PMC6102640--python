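"""Logistic tagging-SNP scans, MDS ancestry axes, LD and hiSNP definition."""

import numpy as np
import pandas as pd
import pytest
from oracle_utils import classical_mds_oracle, haplotype_r2, two_by_two_log_or
from scipy.special import expit

from ervscan.association import (
    GenotypeTable,
    compare_hisnp_sets,
    compute_mds,
    define_hisnps,
    fit_logistic,
    ibs_distance,
    ld_r2,
    prune_and_thin,
    records_to_frame,
    scan_site,
)
from ervscan.errors import DegenerateStatisticError, InputError


def _table(dosage, chrom="chr1", pops=None, inds=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    m, n = dosage.shape
    inds = inds or [f"I{j}" for j in range(n)]
    snps = pd.DataFrame({
        "id": [f"rs{j}" for j in range(m)], "chrom": chrom,
        "pos": np.arange(m) * 1000 + 500, "ref": "A", "alt": "G",
    })
    return GenotypeTable(snps, dosage, inds, pops)


# ----------------------------------------------------------- fit_logistic


def test_no_covariate_binary_dosage_matches_2x2_log_odds(rng):
    for _ in range(10):
        x = (rng.random(300) < 0.4).astype(float)
        y = (rng.random(300) < expit(-0.5 + 0.8 * x)).astype(float)
        if len(np.unique(y)) < 2 or min(
            ((y == a) & (x == b)).sum() for a in (0, 1) for b in (0, 1)
        ) == 0:
            continue
        rec = fit_logistic(y, x)
        assert rec.method == "mle"
        assert rec.beta == pytest.approx(two_by_two_log_odds := two_by_two_log_or(y, x),
                                         rel=1e-8)
        assert rec.odds_ratio == pytest.approx(np.exp(two_by_two_log_odds), rel=1e-8)


def test_matches_statsmodels_glm(rng):
    """Coefficients, standard-error-based p: 1e-6 relative agreement."""
    import statsmodels.api as sm

    for _ in range(10):
        n = 250
        cov = rng.normal(size=(n, 3))
        d = rng.binomial(2, 0.35, size=n).astype(float)
        eta = -0.3 + 0.5 * d + cov @ np.array([0.3, -0.2, 0.1])
        y = (rng.random(n) < expit(eta)).astype(float)
        rec = fit_logistic(y, d, cov)
        x = np.column_stack([np.ones(n), d, cov])
        sm_fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(tol=1e-12)
        assert rec.beta == pytest.approx(sm_fit.params[1], rel=1e-6)
        assert rec.p_value == pytest.approx(sm_fit.pvalues[1], rel=1e-6)


def test_single_class_outcome_raises():
    with pytest.raises(DegenerateStatisticError):
        fit_logistic(np.ones(50), np.arange(50, dtype=float))


def test_complete_separation_falls_back_to_firth():
    rng = np.random.default_rng(3)
    d = rng.binomial(2, 0.4, size=120).astype(float)
    y = (d >= 1).astype(float)  # perfect tagging: carrier <=> dosage >= 1
    rec = fit_logistic(y, d)
    assert rec.method == "firth" and rec.converged
    assert np.isfinite(rec.beta) and rec.beta > 0
    assert rec.p_value < 1e-10


def test_constant_dosage_is_flagged_failed():
    y = np.array([0, 1] * 25, dtype=float)
    rec = fit_logistic(y, np.ones(50))
    assert rec.method == "failed" and not rec.converged and np.isnan(rec.p_value)


def test_null_wald_p_is_calibrated(rng):
    """Independent dosage: type-I error at alpha=0.05 within binomial 99% CI."""
    n, reps, hits = 400, 400, 0
    for _ in range(reps):
        d = rng.binomial(2, 0.3, size=n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        rec = fit_logistic(y, d)
        if rec.converged and rec.p_value < 0.05:
            hits += 1
    ci = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert hits / reps < 0.05 + ci + 0.01


# ------------------------------------------------------------------- MDS


def test_mds_matches_dense_eigendecomposition(rng):
    dosage = rng.binomial(2, 0.4, size=(120, 30)).astype(np.int8)
    table = _table(dosage)
    coords = compute_mds(table, k=4)
    oracle = classical_mds_oracle(ibs_distance(dosage), 4)
    # sign convention may differ per axis; compare up to sign
    for c in range(4):
        assert (np.allclose(coords[:, c], oracle[:, c], atol=1e-8)
                or np.allclose(coords[:, c], -oracle[:, c], atol=1e-8))


def test_mds_first_axis_separates_divergent_populations(rng):
    """Allele-frequency difference of 0.5 between groups: axis 1 splits them
    with group means > 4 SD apart and zero overlap."""
    n_per, m = 40, 300
    p1, p2 = 0.2, 0.7
    g1 = rng.binomial(2, p1, size=(m, n_per))
    g2 = rng.binomial(2, p2, size=(m, n_per))
    table = _table(np.hstack([g1, g2]))
    coords = compute_mds(table, k=2)
    a, b = coords[:n_per, 0], coords[n_per:, 0]
    if a.mean() > b.mean():
        a, b = b, a
    sd = max(a.std(), b.std(), 1e-12)
    assert (b.mean() - a.mean()) / sd > 4
    assert a.max() < b.min()


def test_mds_identical_individuals_all_zero():
    dosage = np.tile(np.array([[1], [2], [0]], dtype=np.int8), (1, 10))
    coords = compute_mds(_table(dosage), k=3)
    assert np.allclose(coords, 0.0)


def test_mds_k_must_be_below_n():
    with pytest.raises(InputError):
        compute_mds(_table(np.zeros((5, 4), dtype=np.int8)), k=4)


# --------------------------------------------------------- prune and thin


def test_prune_removes_monomorphic_and_duplicate_snps(rng):
    base = rng.binomial(2, 0.5, size=(1, 100)).astype(np.int8)
    dosage = np.vstack([
        np.zeros((1, 100), dtype=np.int8),  # monomorphic
        base, base,                          # identical pair, r^2 = 1
        rng.binomial(2, 0.5, size=(40, 100)).astype(np.int8),
    ])
    out = prune_and_thin(_table(dosage), thin_fraction=1.0, seed=0)
    kept = set(out.snps["id"])
    assert "rs0" not in kept
    assert not {"rs1", "rs2"} <= kept  # at most one of the duplicates


def test_thinning_count_and_seed_determinism(rng):
    dosage = rng.binomial(2, 0.5, size=(1000, 60)).astype(np.int8)
    t = _table(dosage)
    out1 = prune_and_thin(t, ld_r2_max=1.1, thin_fraction=0.10, seed=42)
    out2 = prune_and_thin(t, ld_r2_max=1.1, thin_fraction=0.10, seed=42)
    out3 = prune_and_thin(t, ld_r2_max=1.1, thin_fraction=0.10, seed=43)
    n_pass_maf = int((np.minimum(m := dosage.mean(1) / 2, 1 - m) > 0.05).sum())
    assert len(out1.snps) == round(0.1 * n_pass_maf)
    assert list(out1.snps["id"]) == list(out2.snps["id"])
    assert list(out1.snps["id"]) != list(out3.snps["id"])


def test_all_snps_removed_is_an_error():
    dosage = np.zeros((5, 40), dtype=np.int8)
    with pytest.raises(InputError):
        prune_and_thin(_table(dosage))


# ---------------------------------------------------------------- LD r^2


def test_ld_r2_identical_and_undefined():
    a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert np.isnan(ld_r2(a, np.ones(6)))


def test_ld_r2_matches_haplotype_closed_form(rng):
    """Dosage r^2 on phased data equals D^2/(p1 q1 p2 q2) computed from the
    underlying haplotypes when dosages are sums of those haplotypes."""
    n_hap = 2000
    ha = (rng.random(n_hap) < 0.4).astype(int)
    flip = rng.random(n_hap) < 0.15
    hb = np.where(flip, 1 - ha, ha)
    da = ha[0::2] + ha[1::2]
    db = hb[0::2] + hb[1::2]
    got = ld_r2(da.astype(float), db.astype(float))
    # composite dosage r^2 is a consistent estimator of haplotype r^2 under
    # random mating (haplotypes paired independently here)
    assert got == pytest.approx(haplotype_r2(ha, hb), abs=0.05)


def test_independent_snps_rarely_exceed_tagging_threshold(rng):
    hits = 0
    reps = 1000
    for _ in range(reps):
        a = rng.binomial(2, 0.3, size=500).astype(float)
        b = rng.binomial(2, 0.6, size=500).astype(float)
        if ld_r2(a, b) > 0.2:
            hits += 1
    assert hits / reps <= 0.01


# ------------------------------------------------------ hiSNP definition


def _records_frame(site_id="s1", pop="EUR", n=100, chrom="chr1"):
    rng = np.random.default_rng(12)
    return pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(n)],
        "site_id": site_id, "population": pop,
        "beta": 0.0, "odds_ratio": 1.0,
        "p_value": rng.random(n),
        "converged": True, "method": "mle",
        "chrom": chrom, "pos": np.linspace(0, 999_000, n).astype(int),
    })


def test_bonferroni_threshold_is_alpha_over_window_count():
    frame = _records_frame(n=100)
    hs = define_hisnps(frame, "s1", "chr1", 500_000, "EUR")
    assert hs.bonferroni_threshold == pytest.approx(0.05 / 100)


def test_hisnp_members_match_brute_force_filter_and_order_invariance():
    frame = _records_frame(n=200)
    frame.loc[5, "p_value"] = 1e-9
    frame.loc[17, "p_value"] = 1e-7
    hs = define_hisnps(frame, "s1", "chr1", 500_000, "EUR")
    half = 500_000
    exp = frame[(frame.pos >= 500_000 - half) & (frame.pos < 500_000 + half)
                & frame.converged
                & (frame.p_value <= 0.05 / len(frame))]
    assert hs.member_ids == set(exp["snp_id"])
    shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert define_hisnps(shuffled, "s1", "chr1", 500_000, "EUR").member_ids == hs.member_ids


def test_all_p_one_gives_empty_members():
    frame = _records_frame(n=50)
    frame["p_value"] = 1.0
    hs = define_hisnps(frame, "s1", "chr1", 500_000, "EUR")
    assert len(hs.members) == 0 and np.isfinite(hs.bonferroni_threshold)


def test_empty_window_flagged_undefined():
    frame = _records_frame(n=10, chrom="chr2")
    hs = define_hisnps(frame, "s1", "chr1", 500_000, "EUR")
    assert np.isnan(hs.bonferroni_threshold) and len(hs.members) == 0


def test_threshold_strictly_decreases_with_window_count():
    prev = np.inf
    for n in (10, 50, 250, 1000):
        hs = define_hisnps(_records_frame(n=n), "s1", "chr1", 500_000, "EUR")
        assert hs.bonferroni_threshold < prev
        prev = hs.bonferroni_threshold


# ------------------------------------------------------------- scan_site


def test_perfect_tag_snp_has_smallest_window_p(genotype_cohort):
    cfg, genotypes, truth = genotype_cohort
    tags = dict(zip(truth.tag_snps["site_id"], truth.tag_snps["snp_id"]))
    thin_mds = np.zeros((len(genotypes.individual_ids), 2))
    site = truth.sites.iloc[3]
    i = truth.sites.index.get_loc(site.name)
    recs = scan_site(site["site_id"], truth.carrier[i].astype(float),
                     genotypes, thin_mds)
    frame = records_to_frame(recs, genotypes)
    for pop in frame["population"].unique():
        sub = frame[(frame.population == pop)
                    & (frame.chrom == site["chrom"])
                    & (frame.pos >= site["pos"] - 500_000)
                    & (frame.pos < site["pos"] + 500_000)]
        best = sub.loc[sub["p_value"].idxmin(), "snp_id"]
        assert best == tags[site["site_id"]]


def test_fixed_site_is_skipped(genotype_cohort):
    _, genotypes, _ = genotype_cohort
    mds = np.zeros((len(genotypes.individual_ids), 2))
    recs = scan_site("fixed", np.ones(len(genotypes.individual_ids)),
                     genotypes, mds)
    assert recs == []


# ------------------------------------------------------------ set overlap


def test_compare_hisnp_sets_counting():
    a = {"rs1", "rs2", "rs3", "rs4"}
    b = {"rs1", "rs2", "rs3", "rs9"}
    out = compare_hisnp_sets(a, b)
    assert out["overlap_a_in_b"] == pytest.approx(0.75)
    assert out["jaccard"] == pytest.approx(3 / 5)
    assert compare_hisnp_sets(a, a)["jaccard"] == 1.0
    assert compare_hisnp_sets(a, {"x"})["overlap_a_in_b"] == 0.0
    assert np.isnan(compare_hisnp_sets(set(), b)["overlap_a_in_b"])
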