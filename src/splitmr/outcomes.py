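"""Socioeconomic outcome coding rules.

Raw questionnaire-style fields (income category, employment status, job
class, deprivation index, tenure, ...) are mapped onto the analyzed
continuous and binary outcomes.  Binary outcomes are 0/1 against an explicit
reference category; individuals outside a contrast (e.g. the unemployed in a
"retired versus employed" contrast) or failing an eligibility rule (e.g. at
or over pension age for labor-market outcomes) are coded missing, and every
row maps to coded-or-missing for every outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INCOME_MIDPOINTS",
    "HIGH_INCOME_CATEGORIES",
    "PENSION_AGE",
    "OutcomeSpec",
    "DEFAULT_OUTCOMES",
    "EQUIVALIZED_INCOME",
    "code_income",
    "tdi_most_deprived_tertile",
    "code_outcomes",
]

# Midpoint (and nominal open-ended) values for the household income bands.
INCOME_MIDPOINTS = {
    "<£18,000": 15_000.0,
    "£18,000 to £30,999": 24_500.0,
    "£31,000 to £51,999": 41_500.0,
    "£52,000 to £100,000": 76_000.0,
    ">£100,000": 150_000.0,
}
HIGH_INCOME_CATEGORIES = {"£52,000 to £100,000", ">£100,000"}

#: State pension age at recruitment: labor-market outcomes are analyzed only
#: below these ages (strictly less than).
PENSION_AGE = {"men": 65.0, "premenopausal": 60.0, "postmenopausal": 60.0}


def code_income(category: str):
    """Midpoint income in pounds and the above-£52,000 indicator for a band."""
    if category not in INCOME_MIDPOINTS:
        raise ValueError(f"unknown income category {category!r}")
    return INCOME_MIDPOINTS[category], int(category in HIGH_INCOME_CATEGORIES)


def tdi_most_deprived_tertile(tdi: np.ndarray) -> np.ndarray:
    """Indicator for the most deprived tertile, cut on the analyzed sample.

    Higher deprivation index = more deprived; the boundary is the upper
    tertile cut point of the non-missing values passed in.
    """
    tdi = np.asarray(tdi, float)
    out = np.full(tdi.shape, np.nan)
    finite = np.isfinite(tdi)
    if finite.sum() == 0:
        return out
    cut = np.quantile(tdi[finite], 2.0 / 3.0)
    out[finite] = (tdi[finite] > cut).astype(float)
    return out


@dataclass
class OutcomeSpec:
    """Declarative description of one analyzed outcome.

    ``rule`` names a built-in coding rule; ``pension_age_restricted`` masks
    individuals at/over the stratum pension age (labor-market outcomes).
    """

    name: str
    type: str  # "continuous" | "binary"
    rule: str
    pension_age_restricted: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in ("continuous", "binary"):
            raise ValueError(f"outcome type must be continuous or binary, got {self.type!r}")


_EMPLOYMENT_CONTRASTS = {
    "homemaker_vs_employed": "homemaker",
    "sick_disabled_vs_employed": "out_of_labor_force",
    "retired_vs_employed": "retired",
    "unemployed_vs_employed": "unemployed",
}


#: Secondary-analysis outcome: per-head household income (size capped at 12).
EQUIVALIZED_INCOME = OutcomeSpec("equivalized_income", "continuous", "income_equivalized", pension_age_restricted=True)

DEFAULT_OUTCOMES = [
    OutcomeSpec("household_income", "continuous", "income_continuous", pension_age_restricted=True),
    OutcomeSpec("income_over_52k", "binary", "income_binary", pension_age_restricted=True),
    OutcomeSpec("tdi", "continuous", "column", params={"column": "tdi"}),
    OutcomeSpec("tdi_most_deprived", "binary", "tdi_tertile"),
    OutcomeSpec("homemaker_vs_employed", "binary", "employment_contrast", pension_age_restricted=True),
    OutcomeSpec("sick_disabled_vs_employed", "binary", "employment_contrast", pension_age_restricted=True),
    OutcomeSpec("retired_vs_employed", "binary", "employment_contrast", pension_age_restricted=True),
    OutcomeSpec("unemployed_vs_employed", "binary", "employment_contrast", pension_age_restricted=True),
    OutcomeSpec("skilled_job", "binary", "column", params={"column": "skilled_job"}),
    OutcomeSpec("degree", "binary", "column", params={"column": "degree"}),
    OutcomeSpec("own_accommodation", "binary", "column", params={"column": "own_accommodation"}),
    OutcomeSpec("cohabiting", "binary", "column", params={"column": "cohabiting"}),
    OutcomeSpec("risk_taker", "binary", "column", params={"column": "risk_taker"}),
    OutcomeSpec("poor_health", "binary", "column", params={"column": "poor_health"}),
    OutcomeSpec("y_continuous", "continuous", "column", params={"column": "y_continuous"}),
    OutcomeSpec("y_binary", "binary", "column", params={"column": "y_binary"}),
]


def _code_one(pheno: pd.DataFrame, spec: OutcomeSpec) -> np.ndarray:
    n = len(pheno)
    if spec.rule == "column":
        col = spec.params["column"]
        if col not in pheno.columns:
            raise ValueError(f"outcome {spec.name!r} references absent column {col!r}")
        return pheno[col].to_numpy(float)
    if spec.rule == "income_continuous":
        return np.array([INCOME_MIDPOINTS.get(c, np.nan) for c in pheno["income_category"]], float)
    if spec.rule == "income_equivalized":
        # household income divided by household size, size capped at 12
        mid = np.array([INCOME_MIDPOINTS.get(c, np.nan) for c in pheno["income_category"]], float)
        size = np.minimum(pheno["household_size"].to_numpy(float), 12.0)
        return mid / np.maximum(size, 1.0)
    if spec.rule == "income_binary":
        return np.array(
            [float(c in HIGH_INCOME_CATEGORIES) if c in INCOME_MIDPOINTS else np.nan for c in pheno["income_category"]],
            float,
        )
    if spec.rule == "tdi_tertile":
        return tdi_most_deprived_tertile(pheno["tdi"].to_numpy(float))
    if spec.rule == "employment_contrast":
        case = _EMPLOYMENT_CONTRASTS[spec.name]
        status = pheno["employment_status"].to_numpy()
        out = np.full(n, np.nan)
        out[status == "employed"] = 0.0
        out[status == case] = 1.0
        return out
    raise ValueError(f"unknown coding rule {spec.rule!r}")


def code_outcomes(pheno: pd.DataFrame, specs=None):
    """Code every outcome for every row of a (single-stratum) phenotype table.

    Returns ``(coded, log)``: a DataFrame of outcome columns (NaN = missing)
    and a per-outcome log of why rows are missing; the logged reasons sum to
    the row count for each outcome.
    """
    if specs is None:
        specs = DEFAULT_OUTCOMES
    needed = {s.rule for s in specs}
    _ = needed  # rules validated per spec in _code_one
    coded = pd.DataFrame(index=pheno.index)
    log: dict[str, dict[str, int]] = {}
    age = pheno["age"].to_numpy(float)
    pension = np.array([PENSION_AGE.get(s, np.inf) for s in pheno["stratum"]], float)
    over_pension = age >= pension
    for spec in specs:
        values = _code_one(pheno, spec)
        uncodable = ~np.isfinite(values)
        masked = np.zeros(len(pheno), dtype=bool)
        if spec.pension_age_restricted:
            masked = over_pension & ~uncodable
            values = np.where(masked, np.nan, values)
        coded[spec.name] = values
        log[spec.name] = {
            "coded": int(np.isfinite(values).sum()),
            "uncodable": int(uncodable.sum()),
            "pension_age_masked": int(masked.sum()),
        }
    return coded, log
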