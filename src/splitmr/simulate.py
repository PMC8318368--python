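"""Synthetic biobank-style cohort generator with known causal structure.

The generator manufactures individual-level data shaped like a large
population biobank: biallelic SNP dosages with block-exchangeable LD, an
exposure (bioavailable testosterone) with a stratum-specific polygenic
architecture, covariates (age, blood-draw hour, recruitment centre, 40
principal-component-like columns), hormone assays (total testosterone, SHBG,
albumin) consistent with the exposure by construction, socioeconomic outcome
fields, exclusion flags, and a ground-truth record of every structural
parameter — so each downstream analysis stage can be validated by parameter
recovery rather than against inaccessible real data.

Structural model
----------------
Within each stratum (men / premenopausal / postmenopausal women), with
``s`` the standardized true-weight causal score and ``U ~ N(0,1)`` a shared
confounder:

    X  = kappa * s + N,     N = delta*U + age/draw-hour trends
                                + edu feedback + e_x,   e_x ~ N(0,1)
    Y0 = (beta / sd(X)) * (X - mean(X)) + theta*U + alpha*P + e_y
    X <- X + reverse_rho * sd(X) * standardized(Y0)      (if reverse_rho != 0)

``kappa`` is chosen so the causal score explains exactly ``h2_score`` of
Var(X); ``beta`` is therefore the causal effect of a one-SD increase in the
exposure on the continuous outcome.  ``P`` is the standardized unweighted
allele count over the causal SNPs (directional pleiotropy when ``alpha != 0``).
Binary outcomes threshold the continuous liability at a configured prevalence,
so true risk differences have a closed form under the linear probability
model.

The latent exposure is mapped affinely onto bioavailable testosterone using
stratum-typical moments, and the total-testosterone assay value is obtained
by inverting the two-binding-site mass balance
(:func:`splitmr.hormones.total_from_free`), so re-deriving free/bioavailable
testosterone from the written assay columns reproduces the simulated exposure
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import hormones

__all__ = [
    "SimConfig",
    "Cohort",
    "STRATA",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "apply_exclusions",
]

STRATA = ("men", "premenopausal", "postmenopausal")

# Stratum-typical summaries (means, SDs) used as simulation anchors:
# bioavailable testosterone (nM), SHBG (nM), albumin (g/L), age (years).
STRATUM_ANCHORS = {
    "men": {"bat": (5.21, 1.54), "shbg": (39.93, 16.74), "albumin": (45.53, 2.61), "age": (57.1, 8.10)},
    "premenopausal": {"bat": (0.37, 0.25), "shbg": (68.07, 32.31), "albumin": (44.91, 2.59), "age": (46.4, 4.24)},
    "postmenopausal": {"bat": (0.36, 0.28), "shbg": (59.45, 28.03), "albumin": (45.05, 2.56), "age": (60.5, 5.38)},
}

# Named sub-stream offsets so each stage draws from its own deterministic
# stream derived from SimConfig.seed.
_STAGE = {
    "genotypes": 11,
    "strata": 12,
    "covariates": 13,
    "effects": 14,
    "exposure": 15,
    "outcome": 16,
    "hormones": 17,
    "education": 18,
    "exclusions": 19,
    "outcomes_misc": 20,
    "split": 21,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE[stage],)))


@dataclass
class SimConfig:
    """Data-generating parameters for one synthetic cohort.

    ``h2_score`` may be a single fraction or a mapping from stratum name to
    fraction (the stratum-specific polygenic architecture).  All nuisance
    knobs (confounding, pleiotropy, reverse causation) default to the values
    a null-effect, confounded world would have: causal effect zero, shared
    confounder loading 0.5 on exposure and outcome.
    """

    n_individuals: int = 20_000
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    h2_score: float | Mapping[str, float] = field(
        default_factory=lambda: {"men": 0.033, "premenopausal": 0.007, "postmenopausal": 0.004}
    )
    n_causal: int = 40
    beta_causal_effect: float = 0.0  # outcome units per SD of exposure
    conf_exposure: float = 0.5
    conf_outcome: float = 0.5
    pleiotropy_alpha: float = 0.0
    reverse_rho: float = 0.0
    strata_props: tuple = (0.513, 0.125, 0.362)
    seed: int = 0
    # realism knobs (per-unit effects on the latent exposure scale)
    age_effect: float = -0.02  # per year of age, negative: declines with age
    hour_effect: float = -0.03  # per hour after midnight, negative: higher in the morning
    binary_prevalence: float = 0.35
    medication_rate: float = 0.048
    missing_assay_rate: float = 0.054
    relatedness_rate: float = 0.0
    oophorectomy_rate: float = 0.17
    # education architecture (reverse-direction analyses)
    n_causal_edu: int = 20
    h2_edu: float = 0.05
    edu_effect_on_exposure: float = 0.0  # SD of exposure per SD of education latent

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_causal + self.n_causal_edu > self.n_snps:
            raise ValueError("n_causal + n_causal_edu cannot exceed n_snps")
        for h2 in self._h2_by_stratum().values():
            if not (0.0 <= h2 < 1.0):
                raise ValueError("h2_score fractions must be in [0, 1)")
            if h2 > 0 and self.n_causal == 0:
                raise ValueError("h2_score > 0 requires n_causal > 0")
        props = np.asarray(self.strata_props, float)
        if props.min() < 0 or not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise ValueError("strata_props must be non-negative and sum to 1")
        for name in ("binary_prevalence", "medication_rate", "missing_assay_rate", "relatedness_rate", "oophorectomy_rate", "h2_edu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    def _h2_by_stratum(self) -> dict:
        if isinstance(self.h2_score, Mapping):
            return {s: float(self.h2_score.get(s, 0.0)) for s in STRATA}
        return {s: float(self.h2_score) for s in STRATA}

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        d["strata_props"] = list(d["strata_props"])
        if isinstance(d["h2_score"], Mapping):
            d["h2_score"] = dict(d["h2_score"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "strata_props" in d:
            d["strata_props"] = tuple(d["strata_props"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# genotypes


def _bvn_cdf(t: float, rho: float) -> float:
    """P(Z1 < t, Z2 < t) for standard bivariate normal with correlation rho."""
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True).cdf([t, t])
    )


def latent_rho_for_dosage_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving dosage correlation ``target_r``.

    Dosages are sums of two independently drawn thresholded haplotypes, so the
    dosage correlation equals the correlation of the allele indicators,
    ``(P11 - maf^2) / (maf (1 - maf))`` with ``P11`` the bivariate-normal
    orthant mass below the MAF threshold.  Thresholding attenuates
    correlation, so the latent rho is inflated by inverting that relation.
    """
    if target_r <= 0.0:
        return 0.0
    if target_r >= 1.0:
        raise ValueError("target correlation must be < 1")
    t = stats.norm.ppf(maf)

    def f(rho):
        p11 = _bvn_cdf(t, rho)
        return (p11 - maf * maf) / (maf * (1.0 - maf)) - target_r

    return float(optimize.brentq(f, 0.0, 0.999999, xtol=1e-10))


def simulate_genotypes(config: SimConfig):
    """Draw the dosage matrix and SNP metadata table.

    Returns ``(genotypes, snps)`` — an ``(n_individuals, n_snps)`` int8 array
    of effect-allele dosages in {0,1,2} and a DataFrame with columns
    ``snp_id, chr, pos, effect_allele, other_allele, maf``.

    LD is block-exchangeable: each block of ``ld_block_size`` consecutive
    SNPs shares a per-haplotype Gaussian factor; dosage correlation within a
    block is calibrated to ``ld_rho`` at the block's mean MAF, and blocks are
    independent.  Blocks are placed 50 Mb apart (beyond any clumping window)
    on chromosomes cycling 1..22, with 100 kb spacing inside a block.
    """
    config.validate()
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    G = np.empty((n, m), dtype=np.int8)
    block_size = config.ld_block_size
    n_blocks = (m + block_size - 1) // block_size
    for b in range(n_blocks):
        j0, j1 = b * block_size, min((b + 1) * block_size, m)
        k = j1 - j0
        block_maf = mafs[j0:j1]
        if config.ld_rho > 0 and k > 1:
            lrho = latent_rho_for_dosage_r(config.ld_rho, float(block_maf.mean()))
        else:
            lrho = 0.0
        thresh = stats.norm.ppf(block_maf)
        dose = np.zeros((n, k), dtype=np.int8)
        for _hap in range(2):
            if lrho > 0:
                common = rng.standard_normal((n, 1))
                z = np.sqrt(lrho) * common + np.sqrt(1.0 - lrho) * rng.standard_normal((n, k))
            else:
                z = rng.standard_normal((n, k))
            dose += (z < thresh[None, :]).astype(np.int8)
        G[:, j0:j1] = dose

    # SNP metadata: block b sits on chromosome (b % 22) + 1 at a 50 Mb offset
    # per block already seen on that chromosome.
    letters = np.array(list("ACGT"))
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    per_chr_count = dict.fromkeys(range(1, 23), 0)
    for b in range(n_blocks):
        c = (b % 22) + 1
        base = per_chr_count[c] * 50_000_000 + 1_000_000
        per_chr_count[c] += 1
        j0, j1 = b * block_size, min((b + 1) * block_size, m)
        chrom[j0:j1] = c
        pos[j0:j1] = base + np.arange(j1 - j0) * 100_000
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(m)],
            "chr": chrom,
            "pos": pos,
            "effect_allele": letters[ea_idx],
            "other_allele": letters[oa_idx],
            "maf": mafs,
        }
    )
    return G, snps


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    """Genotypes + phenotype table + ground truth for one simulated cohort.

    ``phenotypes`` is indexed 0..n-1 and aligned row-wise with ``genotypes``.
    ``ground_truth`` holds scalars/small lists under ``"params"`` and
    per-individual arrays under ``"individual"`` (a DataFrame); it is present
    only for simulated cohorts.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    phenotypes: pd.DataFrame
    ground_truth: dict | None = None
    config: SimConfig | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def subset(self, row_idx) -> "Cohort":
        row_idx = np.asarray(row_idx)
        gt = None
        if self.ground_truth is not None:
            gt = dict(self.ground_truth)
            gt["individual"] = self.ground_truth["individual"].iloc[row_idx].reset_index(drop=True)
        return Cohort(
            genotypes=self.genotypes[row_idx],
            snps=self.snps,
            phenotypes=self.phenotypes.iloc[row_idx].reset_index(drop=True),
            ground_truth=gt,
            config=self.config,
        )

    # -- directory round trip (plain text) ----------------------------------
    def write_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "genotypes.tsv", self.genotypes, fmt="%d", delimiter="\t")
        # %.17g guarantees a lossless float64 text round trip
        self.snps.to_csv(path / "snps.tsv", sep="\t", index=False, float_format="%.17g")
        self.phenotypes.to_csv(path / "phenotypes.tsv", sep="\t", index=False, float_format="%.17g")
        if self.ground_truth is not None:
            params = {k: v for k, v in self.ground_truth.items() if k != "individual"}
            (path / "ground_truth.json").write_text(json.dumps(params, indent=1))
            self.ground_truth["individual"].to_csv(
                path / "ground_truth_individual.tsv", sep="\t", index=False, float_format="%.17g"
            )
        if self.config is not None:
            self.config.to_yaml(path / "config.yaml")

    @classmethod
    def read_dir(cls, path) -> "Cohort":
        path = Path(path)
        G = np.loadtxt(path / "genotypes.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
        snps = pd.read_csv(path / "snps.tsv", sep="\t", float_precision="round_trip")
        pheno = pd.read_csv(path / "phenotypes.tsv", sep="\t", float_precision="round_trip")
        gt = None
        if (path / "ground_truth.json").exists():
            gt = json.loads((path / "ground_truth.json").read_text())
            gt["individual"] = pd.read_csv(path / "ground_truth_individual.tsv", sep="\t", float_precision="round_trip")
        cfg = SimConfig.from_yaml(path / "config.yaml") if (path / "config.yaml").exists() else None
        return cls(genotypes=G, snps=snps, phenotypes=pheno, ground_truth=gt, config=cfg)


# ---------------------------------------------------------------------------
# phenotypes


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(genotypes: np.ndarray, snps: pd.DataFrame, config: SimConfig) -> Cohort:
    """Attach covariates, exposure, hormones, outcomes and flags to genotypes."""
    config.validate()
    n = genotypes.shape[0]
    if n != config.n_individuals:
        raise ValueError("genotype matrix does not match config.n_individuals")
    h2 = config._h2_by_stratum()

    # strata ---------------------------------------------------------------
    rng = _rng(config.seed, "strata")
    stratum_idx = rng.choice(len(STRATA), size=n, p=np.asarray(config.strata_props, float))
    stratum = np.array(STRATA)[stratum_idx]

    # covariates -----------------------------------------------------------
    rng = _rng(config.seed, "covariates")
    age = np.empty(n)
    for s in STRATA:
        mask = stratum == s
        mu, sd = STRATUM_ANCHORS[s]["age"]
        age[mask] = np.clip(rng.normal(mu, sd, size=mask.sum()), 40.0, 70.0)
    draw_hour = rng.uniform(8.0, 20.0, size=n)
    centre = np.array([f"centre{c:02d}" for c in rng.integers(0, 22, size=n)])
    pcs = rng.standard_normal((n, 40))

    # effect sizes ---------------------------------------------------------
    rng = _rng(config.seed, "effects")
    causal_idx = np.sort(rng.choice(config.n_snps, size=config.n_causal, replace=False))
    remaining = np.setdiff1d(np.arange(config.n_snps), causal_idx)
    edu_idx = np.sort(rng.choice(remaining, size=min(config.n_causal_edu, remaining.size), replace=False))
    gamma = rng.standard_normal(config.n_causal)
    gamma_edu = rng.standard_normal(edu_idx.size)

    # education latent (own architecture, disjoint SNPs) ---------------------
    rng = _rng(config.seed, "education")
    if edu_idx.size and config.h2_edu > 0:
        s_edu = _standardize(genotypes[:, edu_idx].astype(float) @ gamma_edu)
    else:
        s_edu = np.zeros(n)
    edu_latent = np.sqrt(config.h2_edu) * s_edu + np.sqrt(1.0 - config.h2_edu) * rng.standard_normal(n)
    edu_latent = _standardize(edu_latent)
    education_years = np.clip(13.0 + 2.5 * edu_latent, 7.0, 20.0)
    degree = (edu_latent > stats.norm.ppf(1.0 - 0.38)).astype(int)

    # exposure and outcome, per stratum --------------------------------------
    rng_x = _rng(config.seed, "exposure")
    rng_y = _rng(config.seed, "outcome")
    U = rng_x.standard_normal(n)
    e_x = rng_x.standard_normal(n)
    e_y = rng_y.standard_normal(n)

    X = np.empty(n)
    Y = np.empty(n)
    y_binary = np.empty(n, dtype=int)
    scale_record: dict[str, dict] = {}
    Gc = genotypes[:, causal_idx].astype(float) if config.n_causal else np.zeros((n, 0))
    raw_score = Gc @ gamma if config.n_causal else np.zeros(n)
    pleio_raw = Gc.sum(axis=1) if config.n_causal else np.zeros(n)

    for s in STRATA:
        mask = stratum == s
        ns = int(mask.sum())
        if ns == 0:
            scale_record[s] = {}
            continue
        s_std = _standardize(raw_score[mask])
        nongenetic = (
            config.conf_exposure * U[mask]
            + config.age_effect * (age[mask] - age[mask].mean())
            + config.hour_effect * (draw_hour[mask] - draw_hour[mask].mean())
            + config.edu_effect_on_exposure * edu_latent[mask]
            + e_x[mask]
        )
        var_n = float(nongenetic.var())
        h2_s = h2[s]
        kappa = float(np.sqrt(h2_s / (1.0 - h2_s) * var_n)) if h2_s > 0 else 0.0
        x = kappa * s_std + nongenetic
        x_sd = float(x.std())
        x_mean = float(x.mean())

        beta_raw = config.beta_causal_effect / x_sd if x_sd > 0 else 0.0
        pleio_std = _standardize(pleio_raw[mask])
        y0 = (
            beta_raw * (x - x_mean)
            + config.conf_outcome * U[mask]
            + config.pleiotropy_alpha * pleio_std
            + e_y[mask]
        )
        if config.reverse_rho != 0.0:
            x = x + config.reverse_rho * x_sd * _standardize(y0)
            x_sd = float(x.std())
            x_mean = float(x.mean())
        X[mask] = x
        Y[mask] = y0
        # liability threshold at configured prevalence (empirical quantile,
        # so the realized prevalence is exact)
        thr = np.quantile(y0, 1.0 - config.binary_prevalence)
        y_binary[mask] = (y0 > thr).astype(int)
        scale_record[s] = {
            "kappa": kappa,
            "var_nongenetic": var_n,
            "x_mean": x_mean,
            "x_sd": x_sd,
            "beta_per_unit": beta_raw,
            "liability_threshold": float(thr),
        }

    # hormone assays ---------------------------------------------------------
    rng = _rng(config.seed, "hormones")
    shbg = np.empty(n)
    albumin = np.empty(n)
    bat = np.empty(n)
    for s in STRATA:
        mask = stratum == s
        if not mask.any():
            continue
        anch = STRATUM_ANCHORS[s]
        shbg[mask] = np.clip(rng.normal(*anch["shbg"], size=mask.sum()), 1.0, None)
        albumin[mask] = np.clip(rng.normal(*anch["albumin"], size=mask.sum()), 20.0, None)
        mu_b, sd_b = anch["bat"]
        x = X[mask]
        bat[mask] = np.clip(mu_b + sd_b * (x - x.mean()) / x.std(), 0.01, None)
    ft = bat / (1.0 + hormones.ALBUMIN_K * albumin)
    total_t = hormones.total_from_free(ft, shbg, albumin)

    # exclusion flags --------------------------------------------------------
    rng = _rng(config.seed, "exclusions")
    flag_medication = (rng.random(n) < config.medication_rate).astype(int)
    flag_missing = (rng.random(n) < config.missing_assay_rate).astype(int)
    flag_related = (rng.random(n) < config.relatedness_rate).astype(int)
    oophorectomy = np.zeros(n, dtype=int)
    post = stratum == "postmenopausal"
    oophorectomy[post] = (rng.random(int(post.sum())) < config.oophorectomy_rate).astype(int)
    missing = flag_missing == 1
    total_t = total_t.copy()
    total_t[missing] = np.nan
    shbg = shbg.copy()
    shbg[missing] = np.nan
    albumin = albumin.copy()
    albumin[missing] = np.nan

    # named socioeconomic outcome fields -------------------------------------
    rng = _rng(config.seed, "outcomes_misc")
    y_std = np.empty(n)
    for s in STRATA:
        mask = stratum == s
        if mask.any():
            y_std[mask] = _standardize(Y[mask])
    income_latent = 0.5 * y_std + np.sqrt(1.0 - 0.25) * rng.standard_normal(n)
    income_gbp = 50_570.0 + 35_328.0 * income_latent
    income_category = np.select(
        [income_gbp < 18_000, income_gbp < 31_000, income_gbp < 52_000, income_gbp <= 100_000],
        ["<£18,000", "£18,000 to £30,999", "£31,000 to £51,999", "£52,000 to £100,000"],
        default=">£100,000",
    )
    tdi = -1.5 + 2.98 * (-0.3 * y_std + np.sqrt(1.0 - 0.09) * rng.standard_normal(n))
    employment_status = rng.choice(
        ["employed", "retired", "out_of_labor_force", "unemployed", "homemaker"],
        size=n,
        p=[0.75, 0.135, 0.045, 0.02, 0.05],
    )
    skilled_job = (0.3 * y_std + rng.standard_normal(n) > stats.norm.ppf(1.0 - 0.83)).astype(int)
    own_accommodation = (0.2 * y_std + rng.standard_normal(n) > stats.norm.ppf(1.0 - 0.91)).astype(int)
    cohabiting = (0.1 * y_std + rng.standard_normal(n) > stats.norm.ppf(1.0 - 0.75)).astype(int)
    household_size = 1 + rng.poisson(1.4, size=n)
    risk_taker = (rng.random(n) < 0.27).astype(int)
    poor_health = (-0.3 * y_std + rng.standard_normal(n) > stats.norm.ppf(1.0 - 0.24)).astype(int)
    birth_north = rng.standard_normal(n)
    birth_east = rng.standard_normal(n)

    pheno = pd.DataFrame(
        {
            "iid": [f"id{i + 1:07d}" for i in range(n)],
            "stratum": stratum,
            "age": age,
            "draw_hour": draw_hour,
            "centre": centre,
            "oophorectomy": oophorectomy,
            "total_testosterone": total_t,
            "shbg": shbg,
            "albumin": albumin,
            "y_continuous": Y,
            "y_binary": y_binary,
            "income_category": income_category,
            "household_size": household_size,
            "tdi": tdi,
            "employment_status": employment_status,
            "skilled_job": skilled_job,
            "degree": degree,
            "own_accommodation": own_accommodation,
            "cohabiting": cohabiting,
            "risk_taker": risk_taker,
            "poor_health": poor_health,
            "education_years": education_years,
            "birth_north": birth_north,
            "birth_east": birth_east,
            "flag_medication": flag_medication,
            "flag_missing_assay": flag_missing,
            "flag_related": flag_related,
        }
    )
    for j in range(40):
        pheno[f"pc{j + 1}"] = pcs[:, j]

    ground_truth = {
        "params": {
            "beta_causal_effect": config.beta_causal_effect,
            "conf_exposure": config.conf_exposure,
            "conf_outcome": config.conf_outcome,
            "pleiotropy_alpha": config.pleiotropy_alpha,
            "reverse_rho": config.reverse_rho,
            "h2_score": h2,
            "causal_snp_ids": [snps["snp_id"].iloc[i] for i in causal_idx],
            "edu_snp_ids": [snps["snp_id"].iloc[i] for i in edu_idx],
            "gamma": gamma.tolist(),
            "gamma_edu": gamma_edu.tolist(),
            "scale_by_stratum": scale_record,
        },
        "individual": pd.DataFrame(
            {"confounder": U, "exposure_latent": X, "outcome_latent": Y, "education_latent": edu_latent}
        ),
    }
    return Cohort(genotypes=genotypes, snps=snps, phenotypes=pheno, ground_truth=ground_truth, config=config)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Convenience wrapper: genotypes + phenotypes in one call."""
    G, snps = simulate_genotypes(config)
    return simulate_phenotypes(G, snps, config)


def apply_exclusions(cohort: Cohort, reasons=("medication", "missing_assay", "related")):
    """Drop flagged individuals (set union over reasons).

    Returns ``(cohort, log)`` where ``log`` maps each reason to the number of
    individuals carrying that flag and ``"removed_total"`` to the union count.
    """
    flag_cols = {r: f"flag_{r}" for r in reasons}
    missing_cols = [c for c in flag_cols.values() if c not in cohort.phenotypes.columns]
    if missing_cols:
        raise ValueError(f"exclusion flags absent from cohort: {missing_cols}")
    flags = cohort.phenotypes[list(flag_cols.values())].to_numpy() == 1
    union = flags.any(axis=1)
    log = {r: int(flags[:, i].sum()) for i, r in enumerate(flag_cols)}
    log["removed_total"] = int(union.sum())
    log["remaining"] = int((~union).sum())
    if log["remaining"] == 0:
        warnings.warn("all individuals excluded; returning empty cohort")
    return cohort.subset(np.flatnonzero(~union)), log
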