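"""Instrument building: splits, association scan, clumping, scores."""

import numpy as np
import pandas as pd
import pytest

from splitmr import gwas
from splitmr.gwas import (
    GenotypeLD,
    InstrumentSet,
    SumStatsError,
    clump,
    compute_pgs,
    read_sumstats,
    run_gwas,
    score_r2,
    split_sample,
    validate_sumstats,
    write_sumstats,
)
from splitmr.simulate import Cohort, SimConfig, simulate_cohort


# ---------------------------------------------------------------------- split


def test_split_is_a_stratified_partition(tiny_cohort):
    s1, s2 = split_sample(tiny_cohort, seed=1)
    ids1 = set(s1.phenotypes["iid"])
    ids2 = set(s2.phenotypes["iid"])
    assert ids1.isdisjoint(ids2)
    assert ids1 | ids2 == set(tiny_cohort.phenotypes["iid"])
    for s in tiny_cohort.phenotypes["stratum"].unique():
        n1 = (s1.phenotypes["stratum"] == s).sum()
        n2 = (s2.phenotypes["stratum"] == s).sum()
        assert abs(n1 - n2) <= 1


def test_split_deterministic_and_seed_sensitive(tiny_cohort):
    a1, _ = split_sample(tiny_cohort, seed=5)
    b1, _ = split_sample(tiny_cohort, seed=5)
    c1, _ = split_sample(tiny_cohort, seed=6)
    assert a1.phenotypes["iid"].equals(b1.phenotypes["iid"])
    assert not a1.phenotypes["iid"].equals(c1.phenotypes["iid"])


def test_split_rejects_tiny_stratum(tiny_cohort):
    one = tiny_cohort.subset(np.array([0]))
    with pytest.raises(ValueError):
        split_sample(one, seed=0)


# ----------------------------------------------------------------------- gwas


def _toy_cohort(G, pheno_cols=None):
    n, m = G.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:03d}" for j in range(m)],
            "chr": 1,
            "pos": np.arange(m) * 1000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": G.mean(axis=0) / 2,
        }
    )
    pheno = pd.DataFrame({"iid": [f"i{k}" for k in range(n)], "stratum": "men"})
    if pheno_cols:
        for k, v in pheno_cols.items():
            pheno[k] = v
    return Cohort(genotypes=G.astype(np.int8), snps=snps, phenotypes=pheno)


def test_perfect_fit_recovers_slope_with_zero_se():
    G = np.array([[0], [1], [2], [1], [0], [2]], dtype=np.int8)
    c = _toy_cohort(G)
    ss = run_gwas(c, 0.5 * G[:, 0].astype(float))
    assert ss["beta"].iloc[0] == pytest.approx(0.5, abs=1e-12)
    assert ss["se"].iloc[0] == pytest.approx(0.0, abs=1e-10)


def test_beta_se_match_normal_equations_on_toy_table():
    G = np.array([[0], [1], [2], [1], [0]], dtype=np.int8)
    y = np.array([1.0, 2.0, 2.5, 2.2, 0.8])
    ss = run_gwas(_toy_cohort(G), y)
    # independent oracle: explicit least squares on [1, g]
    X = np.column_stack([np.ones(5), G[:, 0]])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = res[0] / 3  # residual df: n - intercept - dosage = 3
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert ss["beta"].iloc[0] == pytest.approx(coef[1], rel=1e-12)
    assert ss["se"].iloc[0] == pytest.approx(se, rel=1e-12)


def test_null_snps_attain_nominal_type_one_error():
    from splitmr.simulate import simulate_genotypes

    cfg = SimConfig(n_individuals=10_000, n_snps=200, n_causal=0, n_causal_edu=0, h2_score=0.0, ld_block_size=1, seed=3)
    G, snps = simulate_genotypes(cfg)
    rng = np.random.default_rng(0)
    y = rng.standard_normal(10_000)
    pheno = pd.DataFrame({"iid": range(10_000), "stratum": "men"})
    c = Cohort(genotypes=G, snps=snps, phenotypes=pheno)
    ss = run_gwas(c, y)
    frac = (ss["p"] < 0.05).mean()
    bound = 3 * np.sqrt(0.05 * 0.95 / len(ss))
    assert abs(frac - 0.05) < bound


def test_constant_snp_skipped_with_warning():
    G = np.array([[1, 0], [1, 1], [1, 2], [1, 1]], dtype=np.int8)
    y = np.array([0.1, 0.4, 0.3, 0.2])
    with pytest.warns(UserWarning, match="constant"):
        ss = run_gwas(_toy_cohort(G), y)
    assert list(ss["snp_id"]) == ["snp001"]


def test_rank_deficient_covariates_rejected():
    G = np.array([[0], [1], [2], [1], [0], [2]], dtype=np.int8)
    y = np.arange(6.0)
    C = np.column_stack([np.ones(6), np.ones(6)])
    with pytest.raises(ValueError, match="rank"):
        run_gwas(_toy_cohort(G), y, C)


def test_sumstats_round_trip_and_validation(tmp_path):
    G = np.array([[0, 2], [1, 1], [2, 0], [1, 2], [0, 1], [2, 2]], dtype=np.int8)
    rng = np.random.default_rng(1)
    y = rng.standard_normal(6)
    ss = run_gwas(_toy_cohort(G), y)
    path = tmp_path / "ss.tsv"
    write_sumstats(ss, path)
    back = read_sumstats(path)
    np.testing.assert_allclose(back["beta"], ss["beta"])
    bad = ss.copy()
    bad.loc[0, "se"] = -1.0
    with pytest.raises(SumStatsError):
        validate_sumstats(bad)
    bad = ss.copy()
    bad.loc[0, "p"] = bad["p"].iloc[0] * 1e-4  # inconsistent with beta/se
    with pytest.raises(SumStatsError, match="inconsistent"):
        validate_sumstats(bad)


# ---------------------------------------------------------------------- clump


def _make_sumstats(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "chr", "pos", "p"])
    df["effect_allele"] = "A"
    df["other_allele"] = "G"
    df["eaf"] = 0.3
    df["beta"] = 0.1
    df["se"] = 0.01
    df["n"] = 1000
    return df


class DictLD:
    def __init__(self, table):
        self.table = table

    def r2(self, a, b):
        return self.table.get((a, b), self.table.get((b, a), 0.0))


def test_clump_empty_when_nothing_significant():
    ss = _make_sumstats([("a", 1, 100, 1e-4), ("b", 1, 200, 1e-6)])
    assert len(clump(ss, DictLD({}))) == 0


def test_clump_discards_correlated_neighbor():
    ss = _make_sumstats([("a", 1, 1000, 1e-10), ("b", 1, 2000, 1e-9)])
    inst = clump(ss, DictLD({("a", "b"): 0.9}))
    assert list(inst.table["snp_id"]) == ["a"]
    # uncorrelated pair is kept even when close
    inst = clump(ss, DictLD({("a", "b"): 0.0005}))
    assert list(inst.table["snp_id"]) == ["a", "b"]
    # far apart (different chromosome) always kept
    ss2 = _make_sumstats([("a", 1, 1000, 1e-10), ("b", 2, 2000, 1e-9)])
    inst = clump(ss2, DictLD({("a", "b"): 0.9}))
    assert list(inst.table["snp_id"]) == ["a", "b"]


def test_clump_invariant_to_row_order():
    rows = [("a", 1, 1000, 1e-10), ("b", 1, 90_000, 1e-9), ("c", 1, 5_000_000, 1e-12), ("d", 2, 100, 1e-8 / 2)]
    ld = DictLD({("a", "b"): 0.5, ("a", "c"): 0.002, ("b", "c"): 0.4})
    ss = _make_sumstats(rows)
    out1 = clump(ss, ld).table["snp_id"].tolist()
    out2 = clump(ss.iloc[::-1].reset_index(drop=True), ld).table["snp_id"].tolist()
    assert out1 == out2


def test_genotype_ld_accessor(tiny_cohort):
    ld = GenotypeLD(tiny_cohort.genotypes, tiny_cohort.snps["snp_id"])
    a, b = tiny_cohort.snps["snp_id"].iloc[0], tiny_cohort.snps["snp_id"].iloc[1]
    ga = tiny_cohort.genotypes[:, 0].astype(float)
    gb = tiny_cohort.genotypes[:, 1].astype(float)
    expected = np.corrcoef(ga, gb)[0, 1] ** 2
    assert ld.r2(a, b) == pytest.approx(expected)
    assert ld.r2(b, a) == pytest.approx(expected)


# ------------------------------------------------------------------------ pgs


def _instruments(records):
    df = pd.DataFrame(records, columns=["snp_id", "effect_allele", "other_allele", "weight"])
    return InstrumentSet(table=df)


def test_pgs_hand_computed_with_resigned_weights():
    G = np.array([[2, 1], [0, 2]], dtype=np.int8)
    snps = pd.DataFrame(
        {"snp_id": ["s1", "s2"], "chr": 1, "pos": [1, 2], "effect_allele": ["A", "C"], "other_allele": ["G", "T"], "maf": 0.3}
    )
    inst = _instruments([("s1", "A", "G", 0.5), ("s2", "C", "T", -0.2)])
    score = compute_pgs(G, snps, inst)
    # s2 weight negative -> count the other allele with weight +0.2
    expected = np.array([0.5 * 2 + 0.2 * (2 - 1), 0.5 * 0 + 0.2 * (2 - 2)])
    np.testing.assert_allclose(score, expected)
    # swapped-allele instrument flips the dosage
    inst_swapped = _instruments([("s1", "G", "A", -0.5), ("s2", "T", "C", 0.2)])
    np.testing.assert_allclose(compute_pgs(G, snps, inst_swapped), expected)


def test_pgs_order_invariance_and_zero_weights(tiny_cohort):
    sub = tiny_cohort.snps.head(4)
    recs = [(r.snp_id, r.effect_allele, r.other_allele, w) for r, w in zip(sub.itertuples(), [0.3, -0.1, 0.2, 0.4])]
    s1 = compute_pgs(tiny_cohort.genotypes, tiny_cohort.snps, _instruments(recs))
    s2 = compute_pgs(tiny_cohort.genotypes, tiny_cohort.snps, _instruments(recs[::-1]))
    np.testing.assert_allclose(s1, s2)
    zero = _instruments([(r[0], r[1], r[2], 0.0) for r in recs])
    np.testing.assert_allclose(compute_pgs(tiny_cohort.genotypes, tiny_cohort.snps, zero), 0.0)


def test_pgs_rejects_missing_or_mismatched_snps(tiny_cohort):
    with pytest.raises(ValueError, match="absent"):
        compute_pgs(tiny_cohort.genotypes, tiny_cohort.snps, _instruments([("nope", "A", "G", 0.1)]))
    r = tiny_cohort.snps.iloc[0]
    bad_allele = {"A", "C", "G", "T"}.difference([r.effect_allele, r.other_allele]).pop()
    with pytest.raises(ValueError, match="mismatch"):
        compute_pgs(tiny_cohort.genotypes, tiny_cohort.snps, _instruments([(r.snp_id, bad_allele, r.other_allele, 0.1)]))


# ------------------------------------------------------------------- score_r2


def test_score_r2_limits():
    rng = np.random.default_rng(2)
    score = rng.standard_normal(20_000)
    y = rng.standard_normal(20_000)
    assert score_r2(score, y) < 0.001
    assert score_r2(score, score) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        score_r2(np.ones(100), rng.standard_normal(100))


def test_split_sample_gwas_betas_agree_across_splits():
    # no systematic split bias: causal-SNP betas from the two halves agree
    cfg = SimConfig(
        n_individuals=8_000, n_snps=20, n_causal=20, n_causal_edu=0, ld_block_size=1,
        h2_score=0.2, strata_props=(1.0, 0.0, 0.0), medication_rate=0.0, missing_assay_rate=0.0, seed=29,
    )
    c = simulate_cohort(cfg)
    x = c.ground_truth["individual"]["exposure_latent"].to_numpy()
    s1, s2 = split_sample(c, seed=1)
    iid_pos = {iid: k for k, iid in enumerate(c.phenotypes["iid"])}
    x1 = np.array([x[iid_pos[i]] for i in s1.phenotypes["iid"]])
    x2 = np.array([x[iid_pos[i]] for i in s2.phenotypes["iid"]])
    ss1 = run_gwas(s1, x1)
    ss2 = run_gwas(s2, x2)
    z = (ss1["beta"] - ss2["beta"]) / np.sqrt(ss1["se"] ** 2 + ss2["se"] ** 2)
    assert (np.abs(z) < 3).mean() >= 0.95
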