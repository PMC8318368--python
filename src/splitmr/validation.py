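"""Monte-Carlo parameter-recovery experiments.

These drive the headline methodological claim: with valid instruments the
split-sample MR estimator recovers the true causal effect and keeps nominal
CI coverage, while under confounding (true effect zero) the multivariable
comparator converges on the omitted-variable-bias slope and MR stays null.
Each replicate builds its instruments the same way the full pipeline does —
discovery-split GWAS, clumping, polygenic score — and estimates in the other
split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwas, mr
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "recovery_config",
    "run_recovery_replicate",
    "recovery_batch",
    "ovb_slope",
    "instrument_strength_f",
    "simulate_summary_stats",
]


def recovery_config(
    beta: float,
    seed: int,
    n: int = 20_000,
    n_instruments: int = 40,
    conf_exposure: float = 0.0,
    conf_outcome: float = 0.0,
    h2: float = 0.033,
) -> SimConfig:
    """Study conditions for one recovery replicate: a single-stratum cohort of
    ``n`` individuals with ``n_instruments`` independent causal SNPs explaining
    ``h2`` of the exposure, no age/draw-hour trends (so the closed-form
    omitted-variable-bias slope applies exactly), and optional confounding."""
    return SimConfig(
        n_individuals=n,
        n_snps=n_instruments,
        n_causal=n_instruments,
        n_causal_edu=0,
        ld_block_size=1,
        ld_rho=0.0,
        maf_range=(0.1, 0.5),
        h2_score=h2,
        beta_causal_effect=beta,
        conf_exposure=conf_exposure,
        conf_outcome=conf_outcome,
        age_effect=0.0,
        hour_effect=0.0,
        strata_props=(1.0, 0.0, 0.0),
        medication_rate=0.0,
        missing_assay_rate=0.0,
        seed=seed,
    )


def ovb_slope(config: SimConfig, truth: dict) -> float:
    """Closed-form omitted-variable-bias slope of outcome on exposure.

    With exposure ``X = kappa*s + delta*U + e`` and outcome
    ``Y = beta_raw*X + theta*U + e_y`` the large-n least-squares slope of Y
    on X is ``beta_raw + delta*theta*Var(U) / Var(X)`` (Var(U) = 1 here).
    """
    scale = truth["params"]["scale_by_stratum"]["men"]
    var_x = scale["x_sd"] ** 2
    return scale["beta_per_unit"] + config.conf_exposure * config.conf_outcome / var_x


def run_recovery_replicate(config: SimConfig) -> dict:
    """Simulate one cohort, build split-sample instruments, estimate IV and OLS.

    The polygenic score is weighted by the discovery-split GWAS betas over
    all SNPs (clumping run with the configured thresholds); the IV and OLS
    estimates come from the other split.  Returns per-unit estimates plus
    the per-replicate ground truth needed for coverage checks.
    """
    cohort = simulate_cohort(config)
    analysis_split, discovery_split = gwas.split_sample(cohort, seed=config.seed)
    ss = gwas.run_gwas(discovery_split, _exposure(discovery_split), None)
    ld = gwas.GenotypeLD(discovery_split.genotypes, discovery_split.snps["snp_id"])
    instruments = gwas.clump(ss, ld, p_threshold=1.0, window_kb=0.0, r2_threshold=1.0)
    score = gwas.compute_pgs(analysis_split.genotypes, analysis_split.snps, instruments)

    x = _exposure(analysis_split)
    y = analysis_split.phenotypes["y_continuous"].to_numpy(float)
    iv = mr.iv_estimate(y, x, score, None)
    ols = mr.multivariable_estimate(y, x, None)
    scale = cohort.ground_truth["params"]["scale_by_stratum"]["men"]
    return {
        "seed": config.seed,
        "beta_true_per_sd": config.beta_causal_effect,
        "beta_true_per_unit": scale["beta_per_unit"],
        "x_sd_true": scale["x_sd"],
        "ovb_slope": ovb_slope(config, cohort.ground_truth),
        "iv_beta": iv.beta,
        "iv_se": iv.se,
        "iv_ci_low": iv.ci_low,
        "iv_ci_high": iv.ci_high,
        "iv_f": iv.f_stat,
        "ols_beta": ols.beta,
        "ols_se": ols.se,
        "n_instruments": len(instruments),
    }


def _exposure(cohort) -> np.ndarray:
    """Latent exposure on its simulation scale (single-stratum cohorts)."""
    return cohort.ground_truth["individual"]["exposure_latent"].to_numpy(float)


def instrument_strength_f(seed: int, n: int = 60_000, h2: float = 0.033) -> dict:
    """Weak-instrument diagnostic at full analysis-split scale.

    Simulates one male-sized split whose true-weight polygenic score explains
    ``h2`` of the exposure variance, then computes the robust first-stage F
    of the score and the incremental R^2 it attains.
    """
    cfg = recovery_config(0.0, seed, n=n, n_instruments=40, h2=h2)
    cohort = simulate_cohort(cfg)
    gamma = np.array(cohort.ground_truth["params"]["gamma"])
    score = cohort.genotypes.astype(float) @ gamma
    x = _exposure(cohort)
    return {"f": mr.first_stage_f(x, score), "r2": gwas.score_r2(score, x), "n": n}


def simulate_summary_stats(
    k: int,
    beta: float,
    alpha: float,
    seed: int,
    bx_range: tuple = (0.05, 0.2),
    se_x: float = 0.005,
    se_y: float = 0.01,
    n_invalid: int = 0,
):
    """Summary-level two-sample MR simulation.

    True SNP-exposure effects are uniform on ``bx_range``; SNP-outcome
    effects are ``beta * bx + alpha`` (``alpha`` applied to all SNPs, or to
    the first ``n_invalid`` only when that is positive), observed with normal
    sampling error at the stated SEs.  Returns two summary-statistics tables
    (exposure, outcome) in the standard schema.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*bx_range, k)
    pleio = np.zeros(k)
    if n_invalid > 0:
        pleio[:n_invalid] = alpha
    else:
        pleio[:] = alpha
    by_true = beta * bx_true + pleio
    bx_hat = bx_true + se_x * rng.standard_normal(k)
    by_hat = by_true + se_y * rng.standard_normal(k)

    def table(betas, ses):
        with np.errstate(divide="ignore"):
            z = np.abs(betas) / np.where(ses > 0, ses, np.nan)
        z = np.where(np.isnan(z), np.inf, z)
        from scipy import stats

        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(k)],
                "chr": 1,
                "pos": np.arange(k) + 1,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": 0.3,
                "beta": betas,
                "se": ses,
                "p": np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0),
                "n": 10_000,
            }
        )

    return table(bx_hat, np.full(k, se_x)), table(by_hat, np.full(k, se_y))


def recovery_batch(n_reps: int, beta: float, seed: int, confounded: bool = False, n: int = 20_000, n_instruments: int = 40) -> pd.DataFrame:
    """Run ``n_reps`` independent recovery replicates; seeds derive from ``seed``."""
    delta = 0.5 if confounded else 0.0
    rows = []
    base = np.random.SeedSequence(entropy=int(seed), spawn_key=(7,))
    child_seeds = base.generate_state(n_reps) % (2**31 - 1)
    for rep_seed in child_seeds:
        cfg = recovery_config(beta, int(rep_seed), n=n, n_instruments=n_instruments, conf_exposure=delta, conf_outcome=delta)
        rows.append(run_recovery_replicate(cfg))
    df = pd.DataFrame(rows)
    df["covers_truth"] = (df["iv_ci_low"] <= df["beta_true_per_unit"]) & (df["beta_true_per_unit"] <= df["iv_ci_high"])
    return df
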