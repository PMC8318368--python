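# Methods

This note documents the models, defaults and design choices behind
`splitmr`, in the order the pipeline uses them.

## Hormone model

Circulating testosterone partitions into free, albumin-bound and SHBG-bound
pools.  With *T* total testosterone (nM), *S* SHBG (nM), *A* albumin (g/L)
and k = 0.5217 the albumin association constant folded into per-gram units,
the mass balance

    T = FT·(1 + k·A) + S·FT/(1 + FT)

treats albumin binding as linear in FT (albumin is far from saturated at
physiological concentrations) and SHBG binding as saturable with unit
affinity on the nM scale.  This is a quadratic in FT; `free_testosterone`
implements its positive root in closed form, and the test suite checks the
closed form against an independent numerical solve of the mass balance to
1e-8 nM.  Bioavailable testosterone is the free plus albumin-bound pool,
BAT = FT·(1 + k·A).  The derivative identity T = FT·(1+kA) + S·FT/(1+FT)
is also exposed as `total_from_free` and used by the simulator (below).

Assay values below the 0.35 nM detection limit are floored *before*
derivation, matching how a laboratory codes sub-limit measurements at the
limit.  FT is clipped to [0, T] with tolerance 1e-12 to guard floating-point
residue at extreme inputs.  Units are enforced at the interface (nM, g/L);
the constant 0.5217 is unit-specific, so no automatic conversion is offered.

A caveat on aggregates: the equation is nonlinear, so the FT implied by a
cohort's *mean* T, S and A is not exactly the mean of per-person FT values.
At male-typical means the two agree to 2 decimals; for premenopausal women
(very low T, high SHBG) the discrepancy can reach the second decimal.

## Synthetic cohort

The generator emulates an adult population biobank in three strata — men,
premenopausal women, postmenopausal women — with proportions
(0.513, 0.125, 0.362).  Anchor moments (means, SDs) for bioavailable
testosterone, SHBG, albumin and age are stratum-typical values: BAT
5.21 (1.54) / 0.37 (0.25) / 0.36 (0.28) nM, SHBG 39.93 (16.74) /
68.07 (32.31) / 59.45 (28.03) nM, albumin ≈45 (2.6) g/L, ages centred at
57 / 46 / 60 years.

**Genotypes.** Biallelic dosages in {0,1,2}, MAF uniform on `maf_range`
(default 0.05–0.5).  LD is block-exchangeable: each block of
`ld_block_size` consecutive SNPs shares one Gaussian factor per haplotype,
and the latent correlation is inflated by inverting the tetrachoric
attenuation at the block's mean MAF so the *dosage* correlation lands on
`ld_rho`.  Blocks are 50 Mb apart on chromosomes cycling 1–22 (outside any
clumping window); SNPs within a block are 100 kb apart.  This is
deliberately not a human LD map: it gives a known, invertible correlation
target so clumping behaviour is testable.

**Exposure.** Within each stratum, with s the standardized true-weight
causal score (weights N(0,1) over `n_causal` SNPs) and U ~ N(0,1) a shared
confounder:

    X = κ·s + N,   N = δ·U + a·(age−mean) + h·(hour−mean) + λ·E + ε,  ε ~ N(0,1)

κ is set to √(h²/(1−h²)·Var(N)), which makes the causal score explain
exactly `h2_score` of Var(X) in the population.  Default per-stratum h²
values are 3.3% / 0.7% / 0.4%, the instrument-strength regime of a large
adult biobank.  Age and draw-hour effects default to negative (a = −0.02
per year, h = −0.03 per hour): testosterone declines with age and across
the day.  E is the education latent (below), entering only when
`edu_effect_on_exposure` ≠ 0.

**Outcome.**  Y = (β/sd(X))·(X−mean) + θ·U + α·P + ε, where β
(`beta_causal_effect`) is the causal effect per SD of exposure, P is the
standardized unweighted causal-allele count (directional pleiotropy when
α ≠ 0), and ε ~ N(0,1).  `reverse_rho` adds a Y→X feedback term
(X ← X + reverse_rho·sd(X)·std(Y)) after Y is formed, so with β = 0 the
genetic instrument remains valid while the observational X–Y association is
non-null.  Binary outcomes threshold Y at the empirical quantile of the
configured prevalence (default 0.35), so true risk differences are
available in closed form for linear-probability-model checks.

The confounder loadings default to δ = θ = 0.5.  These are illustrative:
no quantitative confounder model exists for this exposure–outcome system,
so the defaults were chosen once to produce an observational bias of
roughly 0.2 SD — large enough to be unmistakable, small enough to be
realistic — and are not calibrated to any empirical estimate.

**Hormone assays.**  BAT is an affine map of X onto the stratum anchors
(clipped at 0.01 nM); FT = BAT/(1+kA) with albumin drawn from its anchor;
T is then manufactured by the inverse mass balance `total_from_free`.
Re-deriving FT/BAT from the written assay columns therefore reproduces the
simulated exposure exactly — the round trip is bit-identical — except for
individuals whose manufactured T falls below the 0.35 nM floor (a few
percent of women, negligible for men), for whom flooring perturbs the
derived exposure slightly, as it would in a real assay.

**Education.**  A second architecture on SNPs disjoint from the
hormone-causal set (default 20 SNPs, h² = 5%) generates an education
latent; degree status (prevalence 0.38) and years of schooling are coded
from it.  `edu_effect_on_exposure` lets education causally raise or lower
the exposure, which the reverse-direction MR should recover.

**Named SEP fields.**  Income category (five bands cut at the real
thresholds from a £ latent loading 0.5 on the outcome), deprivation index,
employment status (multinomial, independent of the structural outcome),
skilled job, degree, tenure, cohabitation, risk-taking and self-rated
health load weakly on the structural outcome so the coding layer and
pipeline orchestration are exercised end-to-end; birth coordinates are
independent of everything (negative controls).  These fields are plumbing
for the outcome-coding rules, not calibrated marginals.

**Exclusions.**  Medication-use (4.8%), missing-assay (5.4%) and
relatedness (0% by default — synthetic individuals are unrelated) flags are
drawn independently; exclusion removes the set union.  Missing-assay
individuals have NaN assay columns.

**Determinism.**  Every stage draws from its own stream derived from
`SimConfig.seed` via named spawn keys, so a config plus seed fixes the
cohort bit-for-bit, and cohorts round-trip through the plain-text directory
format losslessly (floats written as %.17g, read with round-trip parsing).

What the simulator does *not* emulate: realistic LD maps and allele
frequency spectra, imputation dosages, population stratification,
relatedness structure, X-chromosome inheritance, informative missingness,
or selection into the cohort.  Passing tests therefore demonstrate that the
estimators do what they claim under their stated assumptions, not that
those assumptions hold in any real biobank.

## GWAS, clumping, score

Per-SNP association is ordinary least squares of the phenotype on dosage
plus covariates (age and the 40 PC-like columns, plus oophorectomy for
postmenopausal women unless toggled off), vectorized by projecting
phenotype and dosages onto the orthogonal complement of the covariate span.
p-values use the t distribution with residual degrees of freedom, which is
exact at small n; at biobank n it is indistinguishable from the normal.
Constant-dosage SNPs are skipped with a warning; missing data are dropped
listwise and logged.

Clumping is greedy: repeatedly keep the smallest-p remaining candidate
below the significance threshold and discard remaining candidates on the
same chromosome within the window (center-to-center) whose r² with it
exceeds the threshold.  Ties in p break by ascending (chromosome,
position), making the result invariant to input row order.  LD is computed
in-sample from the genotype matrix of the same split that produced the
summary statistics.  Defaults: p < 5×10⁻⁸, window 10,000 kb, r² 0.001.

The polygenic score uses raw per-allele betas as weights, re-signed so
every weight is positive toward higher exposure (the counted allele flips
to 2−g where needed).  Scores are always built in the split *opposite* the
discovery GWAS: weights estimated and applied in the same sample would
overfit, biasing the MR toward the observational estimate.

## One-sample MR and comparators

The causal estimator is 2SLS with the score as single instrument.  For
linear models with one instrument this is numerically identical to the
additive structural mean model estimator — an equivalence, not an
approximation — so the coefficient is reported as the causal mean (or
risk) difference per unit of exposure.  Binary outcomes are fitted as
linear probability models for comparability, and standardized results are
×100 (absolute percentage points) per SD of exposure, with the SD estimated
within stratum.

Standard errors are HC1 sandwich throughout (the heteroskedasticity-robust
flavour with n/(n−k) small-sample scaling; software defaults differ in
flavour, and HC1 is the most common).  The 2SLS sandwich uses the
structural residual y − Xβ̂ with the observed exposure.  The
weak-instrument diagnostic is the robust first-stage F — with one
instrument, the squared robust t of the score — reported on every IV
estimate and flagged below a configurable floor (default 10) without
aborting.

The covariate set for estimation is centred cubic polynomials in age and
blood-draw hour, recruitment-centre indicators and the 40 PCs.  Centering
before powering is purely for numerical conditioning.

Differences between MR and multivariable estimates are tested two ways:
Hausman within a split, (b_IV − b_OLS)²/(se_IV² − se_OLS²) against χ²₁,
reported as undefined (not an exception) when the variance difference is
non-positive; and a Fisher z-test (b₁−b₂)/√(se₁²+se₂²) between the
meta-analyzed estimates.  The Fisher form assumes the two estimates are
independent; applied to estimates from the same individuals it is
approximate, and is implemented as specified with this limitation noted.
Splits are combined by fixed-effect (inverse-variance) meta-analysis with
the between-split Cochran Q reported.  All tests are two-sided; no
multiplicity correction is applied.

## Two-sample sensitivity estimators

Wald ratios use first-order SEs (se_outcome/|beta_exposure|), ignoring
exposure-side sampling error — the standard no-measurement-error style
simplification, adequate for strong instruments and the source of small
discrepancies against exact-ratio SEs.  IVW is the precision-weighted mean
of the ratios (identical to the zero-intercept weighted regression of
outcome on exposure betas, an identity the tests assert against the
meta-analysis module to 1e-10).  When Q/df > 1 the IVW SE is inflated by
√(Q/df) — multiplicative random effects, never deflation.

MR-Egger re-orients exposure betas positive (flipping outcome betas with
them) and adds a free intercept; the intercept estimates average
directional pleiotropy.  Residual overdispersion inflates the covariance
multiplicatively with a floor at 1, and p-values use the t distribution
with k−2 df; this combination gives slightly conservative intercept
calibration at moderate k, verified by simulation in the test suite.

The weighted median interpolates the ratio at cumulative standardized
weight 0.5; the weighted mode maximizes a weight-scaled normal-kernel
density whose bandwidth is `bandwidth_factor` × 0.9·(1.4826·MAD)·k^(−1/5)
(zero spread returns the common ratio).  Both get SEs from a seeded
parametric bootstrap of the summary statistics, default 1,000 replicates;
the bandwidth factor defaults to 1.0 and is config-exposed because no
canonical value exists.

Harmonization aligns outcome betas to the exposure's effect alleles,
negating where alleles are swapped (including after strand
complementation) and dropping irreconcilable pairs with a reason.
Palindromic (A/T, C/G) SNPs are retained by default — synthetic strands
are unambiguous — with a strictness flag to drop them for real-format
inputs.

## Outcome coding and orchestration

Income bands map to midpoints (<£18,000 → £15,000; £18,000–30,999 →
£24,500; £31,000–51,999 → £41,500; £52,000–100,000 → £76,000; >£100,000 →
£150,000) with a ≥£52,000 dichotomy.  Deprivation is dichotomized at the
upper tertile cut computed on the non-missing analyzed rows of the stratum
(the quantile population is otherwise unspecified; this is the package's
choice).  Employment is four contrasts against a shared "employed"
reference, each dropping the other non-reference categories.  Labor-market
outcomes (income, employment) are masked for individuals at or over the
stratum pension age — strictly under 60 (women) / 65 (men) at recruitment
are analyzed.  Coding is total: every row maps to coded-or-missing for
every outcome, and missingness reasons are logged and sum to the row count.

The pipeline runs per stratum: exclusions → hormone derivation → split →
GWAS per split → clump → PGS in the opposite split → per-split IV and
multivariable estimates with F and Hausman → meta-analysis → Fisher →
sensitivity suite per split and meta-analyzed.  Postmenopausal GWAS adjust
for oophorectomy by default (toggleable for the secondary specification).
A config plus seed determines every number in the output bundle, which
serializes as one results table, one comparisons table and a structured
provenance document — no binary formats.

## Validation experiments and problem sizes

The Monte-Carlo experiments use single-stratum cohorts of n = 20,000 with
40 independent causal SNPs explaining 3.3% of exposure variance and
instruments built by discovery-split GWAS, a size at which one replicate
runs in well under a second and 200 replicates characterize bias and
coverage to Monte-Carlo error of a few percent.  The instrument-strength
check uses one split of n = 60,000 (a male-sized analysis split), where a
3.3%-R² score yields a robust first-stage F near n·R²/(1−R²) ≈ 2,000.
Pleiotropy-diagnostic calibration runs at the summary-statistics level
(30 SNPs, 200 replicates), which is where those estimators live.

## Known limitations

* Weighted-median/mode SEs are bootstrap-based and inherit bootstrap noise;
  seeds are explicit everywhere.
* The Fisher comparison treats MR and multivariable estimates as
  independent (see above).
* The simulator's named SEP fields are structural plumbing, not calibrated
  joint distributions; only the structural exposure/outcome pair carries
  the ground-truth causal contract.
* Flooring manufactured total-testosterone values at the detection limit
  slightly censors the exposure in the low-testosterone strata.
* Single-instrument 2SLS only; multi-instrument individual-level MR is out
  of scope (the sensitivity suite covers multi-SNP estimation at summary
  level), as are logistic models and within-family designs.
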