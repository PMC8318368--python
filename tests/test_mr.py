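"""One-sample MR estimators: algebraic identities, oracles, meta-analysis."""

import numpy as np
import pytest
from scipy import stats

from splitmr.mr import (
    EstimateResult,
    covariate_design,
    first_stage_f,
    fisher_difference_test,
    hausman_test,
    iv_estimate,
    meta_fixed,
    multivariable_estimate,
    standardize_per_sd,
)


def _est(beta, se, scale="per-unit", **kw):
    return EstimateResult(beta=beta, se=se, p=1.0, n=100, method="MR-2SLS", scale=scale, **kw)


# ----------------------------------------------------------------------- 2SLS


def test_single_instrument_2sls_equals_wald_ratio():
    rng = np.random.default_rng(0)
    n = 2_000
    z = rng.standard_normal(n)
    x = 0.5 * z + rng.standard_normal(n)
    y = 0.3 * x + rng.standard_normal(n)
    est = iv_estimate(y, x, z)
    wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
    assert est.beta == pytest.approx(wald, rel=1e-10)


def test_exposure_equal_to_instrument_reduces_to_ols():
    rng = np.random.default_rng(1)
    n = 500
    x = rng.standard_normal(n)
    y = 0.7 * x + rng.standard_normal(n)
    est_iv = iv_estimate(y, x, x)
    est_ols = multivariable_estimate(y, x)
    assert est_iv.beta == pytest.approx(est_ols.beta, rel=1e-10)


def test_2sls_matches_explicit_two_stage_construction():
    # 6-row toy: hand-built two-regression 2SLS as the oracle
    z = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
    C = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])[:, None]
    x = np.array([0.2, 0.9, 2.1, 0.1, 1.3, 1.8])
    y = np.array([0.5, 1.0, 2.0, 0.3, 1.4, 1.9])
    # stage 1: x on [1, C, z]; stage 2: y on [1, C, xhat]
    Z = np.column_stack([np.ones(6), C, z])
    xhat = Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    X2 = np.column_stack([np.ones(6), C, xhat])
    expected = np.linalg.lstsq(X2, y, rcond=None)[0][-1]
    est = iv_estimate(y, x, z, C)
    assert est.beta == pytest.approx(expected, rel=1e-10)


def test_2sls_coefficient_matches_statsmodels_iv():
    # independent cross-check against the statsmodels sandbox implementation
    from statsmodels.sandbox.regression.gmm import IV2SLS

    rng = np.random.default_rng(2)
    n = 800
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    x = 0.6 * z + u + rng.standard_normal(n)
    y = 0.25 * x + u + rng.standard_normal(n)
    C = rng.standard_normal((n, 2))
    exog = np.column_stack([np.ones(n), C, x])
    instr = np.column_stack([np.ones(n), C, z])
    ref = IV2SLS(y, exog, instrument=instr).fit()
    est = iv_estimate(y, x, z, C)
    assert est.beta == pytest.approx(ref.params[-1], rel=1e-8)


def test_collinear_covariates_rejected():
    rng = np.random.default_rng(3)
    n = 50
    z = rng.standard_normal(n)
    x = z + rng.standard_normal(n)
    y = rng.standard_normal(n)
    C = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(ValueError, match="collinear"):
        iv_estimate(y, x, z, C)
    with pytest.raises(ValueError, match="collinear"):
        multivariable_estimate(y, x, np.column_stack([x, x]))


def test_weak_instrument_flagged_not_fatal():
    rng = np.random.default_rng(4)
    n = 300
    z = rng.standard_normal(n)
    x = rng.standard_normal(n)  # instrument irrelevant
    y = rng.standard_normal(n)
    est = iv_estimate(y, x, z, weak_f_floor=10.0)
    assert est.weak_instrument is True
    assert np.isfinite(est.beta)


# --------------------------------------------------------------- first stage


def test_first_stage_f_closed_form_magnitude():
    rng = np.random.default_rng(5)
    n = 60_000
    r2 = 0.033
    score = rng.standard_normal(n)
    x = np.sqrt(r2) * score + np.sqrt(1 - r2) * rng.standard_normal(n)
    f = first_stage_f(x, score)
    expected = (n - 2) * r2 / (1 - r2)
    assert f == pytest.approx(expected, rel=0.15)
    assert f > 1000


def test_first_stage_f_null_distribution_median():
    rng = np.random.default_rng(6)
    fs = []
    for _ in range(200):
        score = rng.standard_normal(1_000)
        x = rng.standard_normal(1_000)
        fs.append(first_stage_f(x, score))
    # F ~ chi2(1) asymptotically under the null; median 0.455
    assert np.median(fs) == pytest.approx(stats.chi2.ppf(0.5, 1), abs=0.15)


def test_first_stage_f_perfect_instrument_diverges():
    x = np.arange(100.0)
    assert first_stage_f(x, x) == np.inf


# ---------------------------------------------------------------- comparison


def test_fisher_difference_examples():
    same = fisher_difference_test(_est(1.0, 0.6), _est(1.0, 0.8))
    assert same.statistic == 0.0 and same.p == 1.0
    t = fisher_difference_test(_est(1.0, 0.6), _est(0.0, 0.8))
    assert t.statistic == pytest.approx(1.0)
    assert t.p == pytest.approx(0.3173, abs=1e-4)
    swapped = fisher_difference_test(_est(0.0, 0.8), _est(1.0, 0.6))
    assert swapped.statistic == pytest.approx(-t.statistic)
    assert swapped.p == pytest.approx(t.p)
    with pytest.raises(ValueError, match="scale"):
        fisher_difference_test(_est(1.0, 0.6), _est(1.0, 0.6, scale="pp-per-SD"))


def test_hausman_examples():
    null = hausman_test(_est(0.5, 0.5), _est(0.5, 0.3))
    assert null.statistic == 0.0 and null.p == 1.0
    t = hausman_test(_est(1.0, 0.5), _est(0.0, 0.3))
    assert t.statistic == pytest.approx(1.0 / 0.16)
    assert t.p == pytest.approx(stats.chi2.sf(6.25, 1), abs=1e-6)
    assert t.p == pytest.approx(0.0124, abs=2e-4)
    undef = hausman_test(_est(1.0, 0.3), _est(0.0, 0.5))
    assert np.isnan(undef.statistic) and "undefined" in undef.note


# ---------------------------------------------------------------------- meta


def test_meta_fixed_hand_calculations():
    m = meta_fixed([_est(0.0, 1.0, outcome="o"), _est(2.0, 1.0, outcome="o")])
    assert m.beta == pytest.approx(1.0)
    assert m.se == pytest.approx(1 / np.sqrt(2))
    same = meta_fixed([_est(0.8, 0.2, outcome="o"), _est(0.8, 0.2, outcome="o")])
    assert same.beta == pytest.approx(0.8)
    assert same.se == pytest.approx(0.2 / np.sqrt(2))
    assert same.q == pytest.approx(0.0)
    inf = meta_fixed([_est(0.8, 0.2, outcome="o"), _est(5.0, np.inf, outcome="o")])
    assert inf.beta == pytest.approx(0.8)
    assert inf.se == pytest.approx(0.2)


def test_meta_fixed_matches_precision_weight_oracle():
    b = np.array([0.3, -0.1])
    se = np.array([0.15, 0.4])
    m = meta_fixed([_est(b[0], se[0], outcome="o"), _est(b[1], se[1], outcome="o")])
    w = 1 / se**2
    assert m.beta == pytest.approx((w * b).sum() / w.sum(), rel=1e-12)
    assert m.se <= se.min()


def test_meta_fixed_rejects_mismatch():
    with pytest.raises(ValueError):
        meta_fixed([_est(0.1, 0.2, outcome="a")])
    with pytest.raises(ValueError, match="scale"):
        meta_fixed([_est(0.1, 0.2, outcome="o"), _est(0.1, 0.2, outcome="o", scale="pp-per-SD")])


# ------------------------------------------------------------------- scaling


def test_standardize_per_sd():
    unit = standardize_per_sd(_est(0.3, 0.1), exposure_sd=1.0)
    assert unit.beta == pytest.approx(0.3) and unit.scale == "per-SD"
    binary = standardize_per_sd(_est(0.004, 0.001, scale="probability-per-unit"), exposure_sd=1.54)
    assert binary.beta == pytest.approx(0.62, abs=0.005)  # percentage points
    assert binary.scale == "pp-per-SD"
    # CI endpoints transform with beta
    e = _est(0.2, 0.05)
    s = standardize_per_sd(e, 2.0)
    assert s.ci_low == pytest.approx(e.ci_low * 2.0)
    assert s.ci_high == pytest.approx(e.ci_high * 2.0)
    with pytest.raises(ValueError):
        standardize_per_sd(e, 0.0)


# ------------------------------------------------------------------- design


def test_covariate_design_shapes(tiny_cohort):
    C = covariate_design(tiny_cohort.phenotypes)
    n_centres = tiny_cohort.phenotypes["centre"].nunique()
    assert C.shape == (tiny_cohort.n, 6 + (n_centres - 1) + 40)
    assert np.all(np.isfinite(C))
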