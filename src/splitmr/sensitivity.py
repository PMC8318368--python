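"""Summary-statistic (two-sample) MR estimators and pleiotropy diagnostics.

Given per-SNP associations with the exposure (from the discovery split) and
with the outcome (from the analysis split), each SNP provides a Wald-ratio
causal estimate ``beta_outcome / beta_exposure``.  The estimators here
combine those ratios under progressively weaker validity assumptions:

* IVW — precision-weighted mean of the ratios (equivalently the
  zero-intercept weighted regression of outcome on exposure betas); assumes
  every SNP is a valid instrument.
* MR-Egger — the same regression with a free intercept; the intercept
  estimates the average directional pleiotropic effect and its test is a
  pleiotropy diagnostic; the slope remains consistent under the InSIDE
  assumption.
* Weighted median — consistent when SNPs carrying at least half the weight
  are valid.
* Weighted mode — consistent when the largest group of SNPs sharing a causal
  estimate is valid (zero modal pleiotropy).

Ratio SEs are first order (``se_outcome / |beta_exposure|``), ignoring
exposure-side sampling error — the standard no-measurement-error style
simplification, adequate when instruments are strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HarmonizedSet",
    "MRMethodResult",
    "harmonize",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "loo_ivw",
]

_Z95 = 1.96
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedSet:
    """Per-SNP exposure and outcome associations on a shared allele orientation.

    ``table`` columns: snp_id, effect_allele, other_allele, beta_exposure,
    se_exposure, beta_outcome, se_outcome, ratio, ratio_se, weight.
    ``dropped`` records (snp_id, reason) pairs for SNPs that could not be
    harmonized.
    """

    table: pd.DataFrame
    dropped: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame, drop_palindromic: bool = False) -> HarmonizedSet:
    """Align outcome betas to the exposure's effect alleles.

    SNPs absent from either table are dropped; outcome betas are negated
    where the effect/other alleles are swapped relative to the exposure
    (including after strand complementation); irreconcilable allele pairs
    and zero exposure betas are dropped with a reason.  Palindromic (A/T,
    C/G) SNPs are kept by default — synthetic alleles are unambiguous by
    construction — and dropped under ``drop_palindromic`` for real-format
    inputs where strand is uncertain.
    """
    dropped: list[tuple[str, str]] = []
    out_by_id = outcome.set_index("snp_id")
    rows = []
    for rec in exposure.itertuples():
        sid = rec.snp_id
        if sid not in out_by_id.index:
            dropped.append((sid, "absent from outcome sumstats"))
            continue
        o = out_by_id.loc[sid]
        e_ea, e_oa = rec.effect_allele, rec.other_allele
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        if drop_palindromic and _is_palindromic(e_ea, e_oa):
            dropped.append((sid, "palindromic"))
            continue
        flip = None
        if (o_ea, o_oa) == (e_ea, e_oa):
            flip = False
        elif (o_ea, o_oa) == (e_oa, e_ea):
            flip = True
        else:
            c_ea, c_oa = _COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)
            if (c_ea, c_oa) == (e_ea, e_oa):
                flip = False
            elif (c_ea, c_oa) == (e_oa, e_ea):
                flip = True
        if flip is None:
            dropped.append((sid, f"irreconcilable alleles {o_ea}/{o_oa} vs {e_ea}/{e_oa}"))
            continue
        if rec.beta == 0:
            dropped.append((sid, "zero exposure beta"))
            continue
        beta_out = -float(o["beta"]) if flip else float(o["beta"])
        rows.append(
            {
                "snp_id": sid,
                "effect_allele": e_ea,
                "other_allele": e_oa,
                "beta_exposure": float(rec.beta),
                "se_exposure": float(rec.se),
                "beta_outcome": beta_out,
                "se_outcome": float(o["se"]),
            }
        )
    table = pd.DataFrame(rows, columns=["snp_id", "effect_allele", "other_allele", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"])
    if len(table):
        table["ratio"] = table["beta_outcome"] / table["beta_exposure"]
        table["ratio_se"] = table["se_outcome"] / table["beta_exposure"].abs()
        table["weight"] = 1.0 / table["ratio_se"] ** 2
    else:
        for c in ("ratio", "ratio_se", "weight"):
            table[c] = pd.Series(dtype=float)
    return HarmonizedSet(table=table, dropped=dropped)


@dataclass
class MRMethodResult:
    method: str  # "IVW", "MR-Egger", "weighted-median", "weighted-mode"
    beta: float
    se: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))


def ivw(h: HarmonizedSet) -> MRMethodResult:
    """Inverse-variance-weighted estimate.

    Precision-weighted mean of the Wald ratios with first-order weights,
    algebraically identical to the zero-intercept regression of outcome betas
    on exposure betas weighted by ``1/se_outcome^2``.  When the heterogeneity
    ratio Q/df exceeds 1 the SE is inflated multiplicatively (never deflated),
    a multiplicative random-effects model.
    """
    t = h.table
    k = len(t)
    if k == 0:
        raise ValueError("empty harmonized set")
    w = t["weight"].to_numpy()
    r = t["ratio"].to_numpy()
    beta = float((w * r).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    q = float((w * (r - beta) ** 2).sum())
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    if q_df > 0 and q / q_df > 1.0:
        se *= float(np.sqrt(q / q_df))
    return MRMethodResult(method="IVW", beta=beta, se=se, p=_norm_p(beta / se), n_snps=k, q=q, q_df=q_df, q_p=q_p)


def egger(h: HarmonizedSet) -> MRMethodResult:
    """MR-Egger regression: weighted regression of outcome on exposure betas
    with a free intercept.

    Exposure betas are re-oriented positive (outcome betas flipped with
    them) so the intercept estimates directional pleiotropy.  Residual
    overdispersion inflates the covariance multiplicatively (floor 1);
    p-values use the t distribution with k - 2 df.
    """
    t = h.table
    k = len(t)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    sign = np.sign(t["beta_exposure"].to_numpy())
    bx = t["beta_exposure"].to_numpy() * sign
    by = t["beta_outcome"].to_numpy() * sign
    w = 1.0 / t["se_outcome"].to_numpy() ** 2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    sigma2 = float((w * resid**2).sum() / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    df = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(coef[1] / se[1]), df))
    p_int = float(2.0 * stats.t.sf(abs(coef[0] / se[0]), df))
    return MRMethodResult(
        method="MR-Egger",
        beta=float(coef[1]),
        se=float(se[1]),
        p=p_slope,
        n_snps=k,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=p_int,
    )


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    r = ratio[order]
    w = weight[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _parametric_boot(h: HarmonizedSet, point_fn, n_boot: int, seed: int) -> float:
    t = h.table
    rng = np.random.default_rng(seed)
    bx = t["beta_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    sx = t["se_exposure"].to_numpy()
    sy = t["se_outcome"].to_numpy()
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(bx.size)
        byb = by + sy * rng.standard_normal(by.size)
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        ratio = byb / bxb
        weight = (np.abs(bxb) / sy) ** 2
        est[b] = point_fn(ratio, weight)
    return float(est.std(ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRMethodResult:
    """Weighted median of the Wald ratios.

    The estimate interpolates the ratio at cumulative standardized weight
    0.5; the SE comes from a seeded parametric bootstrap of the summary
    statistics.
    """
    t = h.table
    k = len(t)
    if k < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    beta = _weighted_median_point(t["ratio"].to_numpy(), t["weight"].to_numpy())
    se = _parametric_boot(h, _weighted_median_point, n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MRMethodResult(method="weighted-median", beta=beta, se=se, p=_norm_p(beta / se), n_snps=k, n_boot=n_boot, seed=seed)


def _weighted_mode_point(ratio: np.ndarray, weight: np.ndarray, bandwidth_factor: float = 1.0, grid_size: int = 512) -> float:
    mad = np.median(np.abs(ratio - np.median(ratio)))
    s = 1.4826 * mad
    if s == 0:
        return float(np.median(ratio))
    bw = bandwidth_factor * 0.9 * s * ratio.size ** (-0.2)
    lo, hi = ratio.min() - 3 * bw, ratio.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = (weight[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / bw) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MRMethodResult:
    """Weighted mode: argmax of a weight-scaled normal-kernel density over the
    Wald ratios, bandwidth proportional to a MAD-based robust spread.

    Zero spread (all ratios identical) returns the common ratio.  The SE
    comes from a seeded parametric bootstrap.
    """
    t = h.table
    k = len(t)
    if k < 3:
        raise ValueError("weighted mode needs at least 3 SNPs")

    def point(r, w):
        return _weighted_mode_point(r, w, bandwidth_factor=bandwidth_factor)

    beta = point(t["ratio"].to_numpy(), t["weight"].to_numpy())
    se = _parametric_boot(h, point, n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MRMethodResult(
        method="weighted-mode", beta=beta, se=se, p=_norm_p(beta / se), n_snps=k, n_boot=n_boot, seed=seed
    )


def cochran_q(h: HarmonizedSet, beta_ref: float):
    """Cochran's Q about a reference estimate.

    ``Q = sum w_i (ratio_i - beta_ref)^2`` with first-order ratio weights;
    df = k - 1; chi-square p.  Returns ``(q, df, p)``.
    """
    t = h.table
    k = len(t)
    if k < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    w = t["weight"].to_numpy()
    r = t["ratio"].to_numpy()
    q = float((w * (r - beta_ref) ** 2).sum())
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def loo_ivw(h: HarmonizedSet) -> pd.DataFrame:
    """Leave-one-out IVW diagnostics: pooled estimate omitting each SNP."""
    t = h.table
    w = t["weight"].to_numpy()
    r = t["ratio"].to_numpy()
    rows = []
    for i in range(len(t)):
        mask = np.ones(len(t), dtype=bool)
        mask[i] = False
        if mask.sum() == 0:
            continue
        beta = float((w[mask] * r[mask]).sum() / w[mask].sum())
        rows.append({"snp_id": t["snp_id"].iloc[i], "ratio": r[i], "weight": w[i], "ivw_without": beta})
    return pd.DataFrame(rows)
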