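"""End-to-end split-sample MR orchestration.

For each stratum (men, premenopausal, postmenopausal women) the pipeline
runs: exclusions -> hormone derivation -> random half-split -> GWAS of the
exposure in each split -> clumping -> polygenic score built in the *other*
split -> per-split 2SLS MR and multivariable comparator with weak-instrument
F and Hausman test -> fixed-effect meta-analysis across the two splits ->
Fisher test of MR vs multivariable after meta-analysis -> two-sample
sensitivity suite (IVW, MR-Egger, weighted median, weighted mode, Cochran Q)
per split with its own meta-analysis.  Everything is seeded; a config plus
seed fully determines every number in the bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gwas, hormones, mr, outcomes as outcomes_mod, sensitivity as sens
from .simulate import Cohort, SimConfig, apply_exclusions, simulate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_pipeline", "negative_control", "reverse_mr"]


@dataclass
class AnalysisConfig:
    """Analysis-stage settings (instrument thresholds, covariates, bootstraps)."""

    p_threshold: float = 5e-8
    window_kb: float = 10_000.0
    r2_threshold: float = 0.001
    weak_f_floor: float = 10.0
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    strata: tuple = ("men", "premenopausal", "postmenopausal")
    oophorectomy_covariate: bool = True
    outcome_specs: list = field(default_factory=lambda: list(outcomes_mod.DEFAULT_OUTCOMES))
    sensitivity_outcomes: tuple | None = ("y_continuous",)  # None = all coded outcomes
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_specs"] = [s["name"] for s in d["outcome_specs"]]
        d["strata"] = list(d["strata"])
        if d["sensitivity_outcomes"] is not None:
            d["sensitivity_outcomes"] = list(d["sensitivity_outcomes"])
        return d


@dataclass
class ReportBundle:
    """All pipeline output: estimate rows, comparison tests and provenance."""

    results: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: dict

    def write(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(path / "results.tsv", sep="\t", index=False)
        self.comparisons.to_csv(path / "comparisons.tsv", sep="\t", index=False)
        (path / "provenance.yaml").write_text(yaml.safe_dump(self.provenance, sort_keys=False))


_RESULT_COLUMNS = [
    "stratum",
    "split",
    "outcome",
    "method",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "n",
    "scale",
    "f_stat",
    "n_snps",
    "q",
    "q_df",
    "q_p",
    "intercept",
    "intercept_se",
    "intercept_p",
]


def _est_row(est, stratum, split, outcome, **extra) -> dict:
    row = dict.fromkeys(_RESULT_COLUMNS, np.nan)
    row.update(
        stratum=stratum,
        split=split,
        outcome=outcome,
        method=est.method,
        beta=est.beta,
        se=est.se,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        p=est.p,
        scale=est.scale,
    )
    row["n"] = getattr(est, "n", np.nan)
    if getattr(est, "f_stat", None) is not None:
        row["f_stat"] = est.f_stat
    if getattr(est, "q", None) is not None:
        row.update(q=est.q, q_df=est.q_df, q_p=est.q_p)
    row.update(extra)
    return row


def _sens_row(res: sens.MRMethodResult, stratum, split, outcome) -> dict:
    row = dict.fromkeys(_RESULT_COLUMNS, np.nan)
    row.update(
        stratum=stratum,
        split=split,
        outcome=outcome,
        method=res.method,
        beta=res.beta,
        se=res.se,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p=res.p,
        scale="per-exposure-unit",
        n_snps=res.n_snps,
    )
    if res.q is not None:
        row.update(q=res.q, q_df=res.q_df, q_p=res.q_p)
    if res.intercept is not None:
        row.update(intercept=res.intercept, intercept_se=res.intercept_se, intercept_p=res.intercept_p)
    return row


def _restrict_snps(cohort: Cohort, snp_ids) -> Cohort:
    idx = cohort.snps.index[cohort.snps["snp_id"].isin(set(snp_ids))].to_numpy()
    return Cohort(
        genotypes=cohort.genotypes[:, idx],
        snps=cohort.snps.iloc[idx].reset_index(drop=True),
        phenotypes=cohort.phenotypes,
        ground_truth=cohort.ground_truth,
        config=cohort.config,
    )


def _gwas_covariates(sub: Cohort, analysis: AnalysisConfig, stratum: str) -> np.ndarray:
    """GWAS adjustment: age plus the 40 PC-like columns (plus oophorectomy for
    postmenopausal women in the main analysis)."""
    pheno = sub.phenotypes
    cols = [pheno["age"].to_numpy(float)[:, None], pheno[[f"pc{j}" for j in range(1, 41)]].to_numpy(float)]
    if stratum == "postmenopausal" and analysis.oophorectomy_covariate:
        cols.append(pheno["oophorectomy"].to_numpy(float)[:, None])
    return np.hstack(cols)


def _meta_or_none(components):
    components = [c for c in components if c is not None]
    if len(components) < 2:
        return None
    return mr.meta_fixed(components)


def _sens_as_estimate(res: sens.MRMethodResult, outcome: str, stratum: str, split: str) -> mr.EstimateResult:
    return mr.EstimateResult(
        beta=res.beta,
        se=res.se,
        p=res.p,
        n=res.n_snps,
        method=res.method,
        outcome=outcome,
        stratum=stratum,
        split=split,
        scale="per-exposure-unit",
    )


def run_full_pipeline(config: SimConfig | None = None, analysis: AnalysisConfig | None = None, cohort: Cohort | None = None) -> ReportBundle:
    """Run the whole split-sample analysis on a simulated (or supplied) cohort."""
    analysis = analysis or AnalysisConfig()
    if cohort is None:
        config = config or SimConfig()
        cohort = simulate_cohort(config)
    cohort, exclusion_log = apply_exclusions(cohort)
    pheno, n_floored = hormones.derive_panel(cohort.phenotypes)
    cohort.phenotypes = pheno
    exposure_col = "bioavailable_testosterone"

    rows: list[dict] = []
    comp_rows: list[dict] = []
    instrument_log: dict[str, list[int]] = {}

    for stratum in analysis.strata:
        mask = (cohort.phenotypes["stratum"] == stratum).to_numpy()
        if mask.sum() < 4:
            continue
        sub = cohort.subset(np.flatnonzero(mask))
        exposure_all = sub.phenotypes[exposure_col].to_numpy(float)
        exposure_sd = float(np.nanstd(exposure_all))
        splits = gwas.split_sample(sub, analysis.seed)
        per_split: dict[str, dict] = {}
        instrument_log[stratum] = []

        for s_idx, (analysis_split, discovery_split) in enumerate([(splits[0], splits[1]), (splits[1], splits[0])]):
            split_label = str(s_idx + 1)
            ss_exp = gwas.run_gwas(
                discovery_split, exposure_col, _gwas_covariates(discovery_split, analysis, stratum)
            )
            ld = gwas.GenotypeLD(discovery_split.genotypes, discovery_split.snps["snp_id"])
            instruments = gwas.clump(
                ss_exp,
                ld,
                p_threshold=analysis.p_threshold,
                window_kb=analysis.window_kb,
                r2_threshold=analysis.r2_threshold,
                source_split=f"{stratum}-discovery{2 - s_idx}",
            )
            instrument_log[stratum].append(len(instruments))
            if len(instruments) == 0:
                per_split[split_label] = {"iv": {}, "ols": {}, "sens": {}}
                continue

            score = gwas.compute_pgs(analysis_split.genotypes, analysis_split.snps, instruments)
            C = mr.covariate_design(analysis_split.phenotypes)
            exposure = analysis_split.phenotypes[exposure_col].to_numpy(float)
            coded, _missing_log = outcomes_mod.code_outcomes(analysis_split.phenotypes, analysis.outcome_specs)

            iv_by_outcome: dict[str, mr.EstimateResult] = {}
            ols_by_outcome: dict[str, mr.EstimateResult] = {}
            for spec in analysis.outcome_specs:
                y = coded[spec.name].to_numpy(float)
                if np.isfinite(y).sum() < C.shape[1] + 3 or np.nanstd(y) == 0:
                    continue
                binary = spec.type == "binary"
                iv = mr.iv_estimate(
                    y, exposure, score, C, weak_f_floor=analysis.weak_f_floor, binary_outcome=binary,
                    outcome=spec.name, stratum=stratum, split=split_label,
                )
                ols = mr.multivariable_estimate(
                    y, exposure, C, binary_outcome=binary, outcome=spec.name, stratum=stratum, split=split_label
                )
                iv = mr.standardize_per_sd(iv, exposure_sd)
                ols = mr.standardize_per_sd(ols, exposure_sd)
                iv_by_outcome[spec.name] = iv
                ols_by_outcome[spec.name] = ols
                rows.append(_est_row(iv, stratum, split_label, spec.name, n_snps=len(instruments)))
                rows.append(_est_row(ols, stratum, split_label, spec.name))
                h = mr.hausman_test(iv, ols)
                comp_rows.append(
                    {
                        "stratum": stratum,
                        "split": split_label,
                        "outcome": spec.name,
                        "test": h.test,
                        "statistic": h.statistic,
                        "p": h.p,
                        "note": h.note,
                    }
                )

            # two-sample sensitivity suite: discovery-split SNP-exposure
            # betas vs analysis-split SNP-outcome betas
            sens_by_outcome: dict[str, dict[str, sens.MRMethodResult]] = {}
            sens_targets = (
                [s.name for s in analysis.outcome_specs if s.name in iv_by_outcome]
                if analysis.sensitivity_outcomes is None
                else [o for o in analysis.sensitivity_outcomes if o in iv_by_outcome]
            )
            if sens_targets:
                inst_cohort = _restrict_snps(analysis_split, instruments.table["snp_id"])
                sens_cov = _gwas_covariates(inst_cohort, analysis, stratum)
                for oname in sens_targets:
                    y = coded[oname].to_numpy(float)
                    ss_out = gwas.run_gwas(inst_cohort, y, sens_cov)
                    h = sens.harmonize(instruments.table, ss_out)
                    if len(h) == 0:
                        continue
                    methods: dict[str, sens.MRMethodResult] = {"IVW": sens.ivw(h)}
                    if len(h) >= 3:
                        methods["MR-Egger"] = sens.egger(h)
                        methods["weighted-median"] = sens.weighted_median(h, n_boot=analysis.n_boot, seed=analysis.seed)
                        methods["weighted-mode"] = sens.weighted_mode(
                            h, bandwidth_factor=analysis.bandwidth_factor, n_boot=analysis.n_boot, seed=analysis.seed
                        )
                    sens_by_outcome[oname] = methods
                    for res in methods.values():
                        rows.append(_sens_row(res, stratum, split_label, oname))

            per_split[split_label] = {"iv": iv_by_outcome, "ols": ols_by_outcome, "sens": sens_by_outcome}

        # meta-analysis across the two splits ------------------------------
        all_outcomes = {o for d in per_split.values() for o in d["iv"]}
        for oname in sorted(all_outcomes):
            iv_meta = _meta_or_none([per_split[s]["iv"].get(oname) for s in per_split])
            ols_meta = _meta_or_none([per_split[s]["ols"].get(oname) for s in per_split])
            if iv_meta is not None:
                rows.append(_est_row(iv_meta, stratum, "meta", oname))
            if ols_meta is not None:
                rows.append(_est_row(ols_meta, stratum, "meta", oname))
            if iv_meta is not None and ols_meta is not None:
                fisher = mr.fisher_difference_test(iv_meta, ols_meta)
                comp_rows.append(
                    {
                        "stratum": stratum,
                        "split": "meta",
                        "outcome": oname,
                        "test": fisher.test,
                        "statistic": fisher.statistic,
                        "p": fisher.p,
                        "note": "",
                    }
                )
        sens_methods = {m for d in per_split.values() for per_out in d["sens"].values() for m in per_out}
        sens_outcomes_seen = {o for d in per_split.values() for o in d["sens"]}
        for oname in sorted(sens_outcomes_seen):
            for method in sorted(sens_methods):
                comps = [
                    _sens_as_estimate(per_split[s]["sens"][oname][method], oname, stratum, s)
                    for s in per_split
                    if oname in per_split[s]["sens"] and method in per_split[s]["sens"][oname]
                ]
                meta = _meta_or_none(comps)
                if meta is not None:
                    rows.append(_est_row(meta, stratum, "meta", oname))

    provenance = {
        "package_version": __version__,
        "sim_config": yaml.safe_load(yaml.safe_dump(dataclasses.asdict(cohort.config))) if cohort.config else None,
        "analysis_config": analysis.to_dict(),
        "exclusions": exclusion_log,
        "n_total_testosterone_floored": int(n_floored),
        "instruments_per_stratum_split": instrument_log,
    }
    results = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    comparisons = pd.DataFrame(comp_rows, columns=["stratum", "split", "outcome", "test", "statistic", "p", "note"])
    return ReportBundle(results=results, comparisons=comparisons, provenance=provenance)


def negative_control(cohort: Cohort, score, covariates=None, coords=("birth_north", "birth_east")):
    """MR and multivariable estimates of the exposure on birth coordinates.

    The coordinates are simulated independent of everything else, so both
    models should be null; a non-null multivariable estimate with a null MR
    estimate flags residual structure in the comparator.  Returns
    ``{coord: (iv_estimate, multivariable_estimate)}``.
    """
    exposure = cohort.phenotypes["bioavailable_testosterone"].to_numpy(float)
    out = {}
    for coord in coords:
        y = cohort.phenotypes[coord].to_numpy(float)
        if np.nanstd(y) == 0:
            raise ValueError(f"coordinate {coord!r} is constant")
        iv = mr.iv_estimate(y, exposure, score, covariates, outcome=coord)
        ols = mr.multivariable_estimate(y, exposure, covariates, outcome=coord)
        out[coord] = (iv, ols)
    return out


def reverse_mr(
    cohort: Cohort,
    analysis: AnalysisConfig | None = None,
    hormone_cols=("bioavailable_testosterone", "free_testosterone", "total_testosterone", "shbg", "albumin"),
    stratum: str | None = None,
):
    """Reverse-direction MR: educational attainment -> hormones.

    Education has its own simulated genetic architecture on SNPs disjoint
    from the hormone-associated set.  One-sample MR instruments degree
    status with an education polygenic score (results per within-stratum
    hormone SD); the two-sample suite (IVW/Egger/median/mode) uses
    SNP-schooling betas from the discovery split against SNP-hormone betas
    from the analysis split, per extra year of schooling.

    Returns a DataFrame of estimate rows.
    """
    analysis = analysis or AnalysisConfig()
    if stratum is not None:
        cohort = cohort.subset(np.flatnonzero((cohort.phenotypes["stratum"] == stratum).to_numpy()))
    if "bioavailable_testosterone" not in cohort.phenotypes.columns:
        pheno, _ = hormones.derive_panel(cohort.phenotypes)
        cohort.phenotypes = pheno
    s1, s2 = gwas.split_sample(cohort, analysis.seed)
    rows = []
    for split_label, (analysis_split, discovery_split) in (("1", (s1, s2)), ("2", (s2, s1))):
        cov_disc = _gwas_covariates(discovery_split, analysis, stratum or "")
        ss_edu = gwas.run_gwas(discovery_split, "education_years", cov_disc)
        ld = gwas.GenotypeLD(discovery_split.genotypes, discovery_split.snps["snp_id"])
        instruments = gwas.clump(
            ss_edu, ld, p_threshold=analysis.p_threshold, window_kb=analysis.window_kb, r2_threshold=analysis.r2_threshold
        )
        if len(instruments) == 0:
            continue
        score = gwas.compute_pgs(analysis_split.genotypes, analysis_split.snps, instruments)
        C = mr.covariate_design(analysis_split.phenotypes)
        degree = analysis_split.phenotypes["degree"].to_numpy(float)
        inst_cohort = _restrict_snps(analysis_split, instruments.table["snp_id"])
        cov_ana = _gwas_covariates(inst_cohort, analysis, stratum or "")
        for hcol in hormone_cols:
            y_raw = analysis_split.phenotypes[hcol].to_numpy(float)
            sd = float(np.nanstd(y_raw))
            if not np.isfinite(sd) or sd == 0:
                continue
            y = y_raw / sd  # per within-stratum SD of the hormone
            iv = mr.iv_estimate(y, degree, score, C, outcome=hcol, split=split_label)
            rows.append(_est_row(iv, stratum or "all", split_label, hcol, n_snps=len(instruments)))
            ss_out = gwas.run_gwas(inst_cohort, y, cov_ana)
            h = sens.harmonize(instruments.table, ss_out)
            if len(h) == 0:
                continue
            methods = [sens.ivw(h)]
            if len(h) >= 3:
                methods.append(sens.egger(h))
                methods.append(sens.weighted_median(h, n_boot=analysis.n_boot, seed=analysis.seed))
                methods.append(
                    sens.weighted_mode(h, bandwidth_factor=analysis.bandwidth_factor, n_boot=analysis.n_boot, seed=analysis.seed)
                )
            for res in methods:
                rows.append(_sens_row(res, stratum or "all", split_label, hcol))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)
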