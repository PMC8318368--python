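"""Split-sample GWAS, greedy LD clumping and polygenic-score construction.

These are the instrument-building stages: the cohort is halved within each
stratum, per-SNP association statistics are estimated in one half (the
discovery split), genome-wide-significant SNPs are clumped to approximate
independence, and their effect sizes weight a polygenic score evaluated in
the *other* half — so the score's weights are independent of the sample in
which causal effects are estimated, avoiding overlap bias between discovery
and analysis samples.

Association model: ordinary least squares of the phenotype on the
effect-allele dosage plus covariates, one SNP at a time, vectorized by first
projecting phenotype and dosages onto the orthogonal complement of the
covariate span.  p-values use the t distribution with residual degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Cohort

__all__ = [
    "SUMSTATS_COLUMNS",
    "SumStatsError",
    "split_sample",
    "run_gwas",
    "validate_sumstats",
    "read_sumstats",
    "write_sumstats",
    "InstrumentSet",
    "GenotypeLD",
    "clump",
    "compute_pgs",
    "score_r2",
]

SUMSTATS_COLUMNS = ["snp_id", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n"]


class SumStatsError(ValueError):
    pass


def split_sample(cohort: Cohort, seed: int):
    """Randomly halve the cohort within each stratum.

    Returns ``(split1, split2)`` with per-stratum sizes differing by at most
    one; for odd strata the extra member lands in split 1 or 2 depending on
    the seed.  Deterministic for a fixed seed.
    """
    stratum = cohort.phenotypes["stratum"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(101,)))
    idx1, idx2 = [], []
    for s in pd.unique(stratum):
        members = np.flatnonzero(stratum == s)
        if members.size < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 members; cannot split")
        perm = rng.permutation(members)
        half = members.size // 2
        if members.size % 2 == 1 and rng.random() < 0.5:
            half += 1
        idx1.append(perm[:half])
        idx2.append(perm[half:])
    idx1 = np.sort(np.concatenate(idx1))
    idx2 = np.sort(np.concatenate(idx2))
    return cohort.subset(idx1), cohort.subset(idx2)


def _as_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    return C


def run_gwas(cohort: Cohort, phenotype, covariates=None) -> pd.DataFrame:
    """Per-SNP least-squares association scan.

    Parameters
    ----------
    cohort : Cohort
    phenotype : str or array_like
        Column name in the phenotype table, or a vector of length n.
    covariates : array_like, optional
        Covariate matrix (without intercept); an intercept is always added.
        Rows with missing phenotype or covariates are dropped listwise.

    Returns
    -------
    DataFrame in the standard summary-statistics schema
    (``snp_id, chr, pos, effect_allele, other_allele, eaf, beta, se, p, n``).
    Constant-dosage SNPs are skipped with a warning.
    """
    y = cohort.phenotypes[phenotype].to_numpy(float) if isinstance(phenotype, str) else np.asarray(phenotype, float)
    n_all = cohort.n
    if y.shape[0] != n_all:
        raise ValueError("phenotype length does not match cohort size")
    C = _as_matrix(covariates, n_all)
    keep = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"listwise deletion removed {n_dropped} rows with missing phenotype/covariates")
    y = y[keep]
    C = C[keep]
    G = cohort.genotypes[keep].astype(float)
    n = y.shape[0]

    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gss = np.einsum("ij,ij->j", G_r, G_r)
    constant = gss <= 1e-12
    if constant.any():
        warnings.warn(f"skipped {int(constant.sum())} constant-dosage SNPs")
    gss_safe = np.where(constant, np.nan, gss)
    beta = (G_r.T @ y_r) / gss_safe
    df = n - X.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough rows for the requested covariate set")
    rss = (y_r @ y_r) - beta**2 * gss_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = cohort.snps[["snp_id", "chr", "pos", "effect_allele", "other_allele"]].copy()
    out["eaf"] = G.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out = out[~constant].reset_index(drop=True)
    return out


def validate_sumstats(sumstats: pd.DataFrame, z_p_rtol: float = 0.5) -> None:
    """Schema and internal-consistency checks for a summary-statistics table.

    beta/se/p consistency is checked against the normal approximation only
    loosely (``z_p_rtol`` relative error on log p), since stored p-values may
    come from a t distribution whose residual df the table does not carry.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in sumstats.columns]
    if missing:
        raise SumStatsError(f"missing sumstats columns: {missing}")
    if (sumstats["se"] <= 0).any():
        raise SumStatsError("all SEs must be positive")
    if ((sumstats["p"] <= 0) | (sumstats["p"] > 1)).any():
        raise SumStatsError("p-values must be in (0, 1]")
    if ((sumstats["eaf"] <= 0) | (sumstats["eaf"] >= 1)).any():
        raise SumStatsError("effect-allele frequencies must be in (0, 1)")
    z = np.abs(sumstats["beta"] / sumstats["se"])
    p_norm = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    log_obs = np.log(sumstats["p"].to_numpy(float))
    log_exp = np.log(p_norm)
    rel = np.abs(log_obs - log_exp) / np.maximum(np.abs(log_exp), 1.0)
    if np.any(rel > z_p_rtol):
        raise SumStatsError("p-values inconsistent with beta/se")


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t")
    validate_sumstats(ss)
    return ss


# ---------------------------------------------------------------------------
# clumping


@dataclass
class InstrumentSet:
    """Clumped genome-wide-significant SNPs with per-allele weights.

    ``table`` keeps the summary-statistics columns plus ``weight`` (the GWAS
    beta for the effect allele), ordered by ascending p.
    """

    table: pd.DataFrame
    source_split: str = ""
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, source_split: str = "", params: dict | None = None) -> "InstrumentSet":
        return cls(table=pd.read_csv(path, sep="\t"), source_split=source_split, params=params or {})


class GenotypeLD:
    """Pairwise r^2 accessor backed by a genotype matrix.

    LD is computed from the same split that produced the summary statistics
    (in-sample LD), lazily and cached per SNP pair.
    """

    def __init__(self, genotypes: np.ndarray, snp_ids) -> None:
        self._G = genotypes
        self._col = {sid: j for j, sid in enumerate(snp_ids)}
        self._cache: dict[tuple, float] = {}

    def r2(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._cache:
            ga = self._G[:, self._col[a]].astype(float)
            gb = self._G[:, self._col[b]].astype(float)
            sa, sb = ga.std(), gb.std()
            if sa == 0 or sb == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(ga, gb)[0, 1])
            self._cache[key] = r * r
        return self._cache[key]

    def __call__(self, a: str, b: str) -> float:
        return self.r2(a, b)


def clump(
    sumstats: pd.DataFrame,
    ld,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000,
    r2_threshold: float = 0.001,
    source_split: str = "",
) -> InstrumentSet:
    """Greedy p-value clumping of genome-wide-significant SNPs.

    Repeatedly retain the smallest-p remaining candidate and discard every
    remaining candidate on the same chromosome within ``window_kb``
    (center-to-center) whose r^2 with it exceeds ``r2_threshold``.  Ties in p
    are broken by ascending (chromosome, position), making the output
    invariant to input row order.

    ``ld`` is any object with an ``r2(snp_id_a, snp_id_b)`` method or a
    callable returning r^2.
    """
    r2_fn = ld.r2 if hasattr(ld, "r2") else ld
    cand = sumstats[sumstats["p"] < p_threshold].copy()
    cand = cand.sort_values(["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)
    kept_rows = []
    alive = np.ones(len(cand), dtype=bool)
    window_bp = window_kb * 1_000
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        row = cand.iloc[i]
        for j in range(i + 1, len(cand)):
            if not alive[j]:
                continue
            other = cand.iloc[j]
            if other["chr"] != row["chr"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_bp:
                continue
            if r2_fn(row["snp_id"], other["snp_id"]) > r2_threshold:
                alive[j] = False
    table = cand.iloc[kept_rows].reset_index(drop=True)
    table["weight"] = table["beta"]
    return InstrumentSet(
        table=table,
        source_split=source_split,
        params={"p_threshold": p_threshold, "window_kb": window_kb, "r2_threshold": r2_threshold},
    )


def compute_pgs(genotypes: np.ndarray, snps: pd.DataFrame, instruments: InstrumentSet) -> np.ndarray:
    """Per-individual polygenic score from an instrument set.

    The score is the weighted sum of exposure-increasing alleles: weights are
    re-signed to be positive, and the counted allele is flipped (dosage
    ``2 - g``) wherever the instrument's effect on the exposure is negative,
    or wherever the instrument's effect allele is the cohort's other allele.
    Missing SNPs or irreconcilable allele pairs raise with the SNP id.
    """
    col = {sid: j for j, sid in enumerate(snps["snp_id"])}
    ea = dict(zip(snps["snp_id"], snps["effect_allele"]))
    oa = dict(zip(snps["snp_id"], snps["other_allele"]))
    score = np.zeros(genotypes.shape[0])
    for rec in instruments.table.itertuples():
        sid = rec.snp_id
        if sid not in col:
            raise ValueError(f"instrument SNP {sid!r} absent from genotypes")
        g = genotypes[:, col[sid]].astype(float)
        if rec.effect_allele == ea[sid] and rec.other_allele == oa[sid]:
            dosage = g
        elif rec.effect_allele == oa[sid] and rec.other_allele == ea[sid]:
            dosage = 2.0 - g
        else:
            raise ValueError(f"allele mismatch for SNP {sid!r}: " f"{rec.effect_allele}/{rec.other_allele} vs {ea[sid]}/{oa[sid]}")
        w = float(rec.weight)
        if w < 0:  # count the exposure-increasing allele instead
            w, dosage = -w, 2.0 - dosage
        score += w * dosage
    return score


def score_r2(score, phenotype, covariates=None) -> float:
    """Incremental R^2 of adding the score to the covariate-only model."""
    score = np.asarray(score, float)
    y = np.asarray(phenotype, float)
    n = y.shape[0]
    C = _as_matrix(covariates, n)
    keep = np.isfinite(y) & np.isfinite(score) & np.all(np.isfinite(C), axis=1)
    y, score, C = y[keep], score[keep], C[keep]
    if score.std() == 0:
        raise ValueError("score is constant")
    X0 = np.column_stack([np.ones(y.shape[0]), C])
    Q, _ = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    s_r = score - Q @ (Q.T @ score)
    denom = float(y_r @ y_r)
    if denom == 0:
        return 0.0
    svar = float(s_r @ s_r)
    if svar <= 1e-12:
        raise ValueError("score is collinear with the covariates")
    beta = float(s_r @ y_r) / svar
    rss = denom - beta**2 * svar
    return 1.0 - rss / denom
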