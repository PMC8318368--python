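"""One-sample Mendelian randomization and its observational comparators.

The causal estimator is two-stage least squares (2SLS) with a single
instrument (the polygenic score) and a shared covariate set: stage 1
regresses the exposure on the score plus covariates, stage 2 regresses the
outcome on the fitted exposure plus covariates.  For linear models with one
instrument this is numerically identical to the additive structural mean
model estimator, so the 2SLS coefficient is reported as the causal mean (or
risk) difference per unit of exposure.  Binary outcomes are fitted
identically as linear probability models, so their coefficients are risk
differences.

Standard errors are heteroskedasticity-consistent (HC1 sandwich) throughout,
with the 2SLS sandwich built from the structural residual ``y - X b`` (the
observed exposure, not its first-stage fit).  The weak-instrument diagnostic
is the robust first-stage F, which with a single instrument is the squared
robust t of the score in stage 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EstimateResult",
    "MetaEstimate",
    "ComparisonTest",
    "covariate_design",
    "iv_estimate",
    "multivariable_estimate",
    "first_stage_f",
    "fisher_difference_test",
    "hausman_test",
    "meta_fixed",
    "standardize_per_sd",
]

_Z95 = 1.96  # conventional two-sided 95% multiplier


@dataclass
class EstimateResult:
    """One effect estimate with its provenance.

    ``scale`` tags the interpretation: ``per-unit`` / ``per-SD`` for
    continuous outcomes, ``probability-per-unit`` / ``pp-per-SD`` (risk
    difference x100) for binary outcomes.
    """

    beta: float
    se: float
    p: float
    n: int
    method: str  # "MR-2SLS" or "multivariable-OLS"
    outcome: str = ""
    stratum: str = ""
    split: str = ""
    scale: str = "per-unit"
    f_stat: float | None = None
    weak_instrument: bool | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se


@dataclass
class MetaEstimate:
    beta: float
    se: float
    p: float
    q: float
    q_df: int
    q_p: float
    components: list = field(default_factory=list)
    method: str = ""
    outcome: str = ""
    stratum: str = ""
    scale: str = "per-unit"

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se


@dataclass
class ComparisonTest:
    statistic: float
    p: float
    test: str  # "Fisher" or "Hausman"
    estimates: tuple = ()
    note: str = ""


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))


def covariate_design(pheno, age_col="age", hour_col="draw_hour", centre_col="centre", pc_cols=None, cubic=True):
    """Standard adjustment set: centered cubic polynomials in age and blood-draw
    hour, recruitment-centre indicators (reference level dropped) and the
    principal-component columns.  Centering before powering is for numerical
    conditioning only; it does not change the exposure coefficient."""
    import pandas as pd

    cols = []
    for c in (age_col, hour_col):
        x = pheno[c].to_numpy(float)
        xc = x - x.mean()
        cols.append(xc)
        if cubic:
            cols.extend([xc**2, xc**3])
    mat = [np.column_stack(cols)]
    if centre_col is not None and centre_col in pheno.columns:
        dummies = pd.get_dummies(pheno[centre_col], drop_first=True).to_numpy(float)
        mat.append(dummies)
    if pc_cols is None:
        pc_cols = [c for c in pheno.columns if c.startswith("pc") and c[2:].isdigit()]
    if pc_cols:
        mat.append(pheno[list(pc_cols)].to_numpy(float))
    return np.hstack(mat)


def _prepare(outcome, exposure, covariates, extra=None):
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    n = y.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    keep = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
    if extra is not None:
        keep &= np.isfinite(np.asarray(extra, float))
    return y[keep], x[keep], C[keep], (None if extra is None else np.asarray(extra, float)[keep])


def _check_rank(M: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(f"collinear {what}")


def iv_estimate(
    y,
    x,
    score,
    covariates=None,
    weak_f_floor: float = 10.0,
    binary_outcome: bool = False,
    **tags,
) -> EstimateResult:
    """2SLS estimate of the exposure effect using the score as instrument.

    A weak first stage (robust F below ``weak_f_floor``) does not abort; the
    result is returned with ``weak_instrument=True``.
    """
    y, x, C, z = _prepare(y, x, covariates, extra=score)
    n = y.shape[0]
    ones = np.ones((n, 1))
    Z = np.hstack([ones, C, z[:, None]])  # full instrument matrix
    X = np.hstack([ones, C, x[:, None]])
    _check_rank(np.hstack([ones, C]), "covariates")
    _check_rank(Z, "instrument matrix (score constant after covariate projection?)")
    k = X.shape[1]

    Qz, _ = np.linalg.qr(Z)
    Xhat = Qz @ (Qz.T @ X)
    XtX = Xhat.T @ X
    beta_all = np.linalg.solve(XtX, Xhat.T @ y)
    u = y - X @ beta_all  # structural residual, observed exposure
    bread = np.linalg.inv(Xhat.T @ Xhat)
    meat = (Xhat * (u**2)[:, None]).T @ Xhat
    cov = bread @ meat @ bread * (n / (n - k))  # HC1 small-sample scaling
    b = float(beta_all[-1])
    se = float(np.sqrt(cov[-1, -1]))

    f = first_stage_f(x, z, C if C.shape[1] else None)
    return EstimateResult(
        beta=b,
        se=se,
        p=_norm_p(b / se) if se > 0 else 0.0,
        n=n,
        method="MR-2SLS",
        scale="probability-per-unit" if binary_outcome else "per-unit",
        f_stat=f,
        weak_instrument=bool(f < weak_f_floor),
        **tags,
    )


def multivariable_estimate(y, x, covariates=None, binary_outcome: bool = False, **tags) -> EstimateResult:
    """Least-squares association of outcome with exposure, HC1 robust SE.

    This is the observational comparator: no genetic instrument, so it is
    vulnerable to confounding and reverse causation in exactly the way the
    MR estimate is not.
    """
    y, x, C, _ = _prepare(y, x, covariates)
    n = y.shape[0]
    X = np.column_stack([np.ones(n), C, x])
    _check_rank(X, "covariates")
    res = sm.OLS(y, X).fit(cov_type="HC1")
    b = float(res.params[-1])
    se = float(res.bse[-1])
    return EstimateResult(
        beta=b,
        se=se,
        p=_norm_p(b / se) if se > 0 else 0.0,
        n=n,
        method="multivariable-OLS",
        scale="probability-per-unit" if binary_outcome else "per-unit",
        **tags,
    )


def first_stage_f(exposure, score, covariates=None) -> float:
    """Robust first-stage F for the single excluded instrument.

    With one instrument this is the squared HC1 t statistic of the score in
    the regression of exposure on score plus covariates.  A perfect first
    stage (zero residual) is reported as ``inf``.
    """
    x, z, C, _ = _prepare(exposure, score, covariates)
    n = x.shape[0]
    X = np.column_stack([np.ones(n), C, z])
    res = sm.OLS(x, X).fit(cov_type="HC1")
    se = float(res.bse[-1])
    if se == 0 or not np.isfinite(se):
        return float("inf")
    f = float((res.params[-1] / se) ** 2)
    # a numerically perfect first stage is reported as divergent
    return f if f < 1e12 else float("inf")


def fisher_difference_test(est1, est2) -> ComparisonTest:
    """z test for a difference between two (independent) estimates.

    ``z = (b1 - b2) / sqrt(se1^2 + se2^2)``, two-sided normal p.  Used to
    compare meta-analyzed MR and multivariable estimates; the independence
    assumption is approximate when both come from the same individuals.
    """
    if est1.scale != est2.scale:
        raise ValueError(f"scale mismatch: {est1.scale!r} vs {est2.scale!r}")
    z = (est1.beta - est2.beta) / np.sqrt(est1.se**2 + est2.se**2)
    return ComparisonTest(statistic=float(z), p=_norm_p(z), test="Fisher", estimates=(est1, est2))


def hausman_test(iv: EstimateResult, ols: EstimateResult) -> ComparisonTest:
    """Hausman test of IV vs OLS within one split.

    ``(b_IV - b_OLS)^2 / (se_IV^2 - se_OLS^2)`` against chi-square(1).  Under
    exogeneity OLS is efficient, so the variance difference should be
    positive; a non-positive difference yields an undefined (NaN) result with
    a reason rather than an exception.
    """
    if iv.scale != ols.scale:
        raise ValueError(f"scale mismatch: {iv.scale!r} vs {ols.scale!r}")
    var_diff = iv.se**2 - ols.se**2
    if var_diff <= 0:
        return ComparisonTest(
            statistic=float("nan"),
            p=float("nan"),
            test="Hausman",
            estimates=(iv, ols),
            note="undefined: Var(IV) <= Var(OLS)",
        )
    stat = (iv.beta - ols.beta) ** 2 / var_diff
    return ComparisonTest(statistic=float(stat), p=float(stats.chi2.sf(stat, df=1)), test="Hausman", estimates=(iv, ols))


def meta_fixed(estimates) -> MetaEstimate:
    """Fixed-effect (inverse-variance) meta-analysis across splits.

    Weights ``1/se^2``; infinite SEs contribute zero weight.  Reports the
    between-component Cochran Q as a heterogeneity check.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("meta-analysis needs at least two estimates")
    scales = {e.scale for e in estimates}
    outcomes = {e.outcome for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"scale mismatch across components: {scales}")
    if len(outcomes) > 1:
        raise ValueError(f"outcome mismatch across components: {outcomes}")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValueError("component SEs must be positive")
    with np.errstate(divide="ignore"):
        w = 1.0 / se**2  # se = inf -> weight 0
    wsum = w.sum()
    pooled = float((w * b).sum() / wsum)
    pooled_se = float(1.0 / np.sqrt(wsum))
    q = float((w * (b - pooled) ** 2).sum())
    q_df = len(estimates) - 1
    return MetaEstimate(
        beta=pooled,
        se=pooled_se,
        p=_norm_p(pooled / pooled_se) if pooled_se > 0 else 0.0,
        q=q,
        q_df=q_df,
        q_p=float(stats.chi2.sf(q, q_df)),
        components=estimates,
        method=estimates[0].method,
        outcome=estimates[0].outcome,
        stratum=estimates[0].stratum,
        scale=estimates[0].scale,
    )


def standardize_per_sd(est, exposure_sd: float):
    """Re-express a per-unit estimate per SD of the exposure.

    beta, SE (and hence both CI endpoints) are multiplied by the exposure SD;
    binary-outcome (risk-difference) results are additionally multiplied by
    100 to absolute percentage points.  Returns a new result object.
    """
    if exposure_sd <= 0:
        raise ValueError("exposure_sd must be positive")
    factor = exposure_sd
    if est.scale == "probability-per-unit":
        factor *= 100.0
        new_scale = "pp-per-SD"
    elif est.scale == "per-unit":
        new_scale = "per-SD"
    else:
        raise ValueError(f"estimate already standardized (scale {est.scale!r})")
    return replace(est, beta=est.beta * factor, se=est.se * factor, scale=new_scale)
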