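"""Return-screening (attrition) cohort construction and odds-ratio models.

From encounter-level records, build one row per woman screened in a
baseline year (2019 for the main analysis, 2018-06-02..12-31 for the
sensitivity analysis) with covariates taken from her first baseline-year
encounter, derive the four return outcomes from calendar-year encounter
presence, and estimate adjusted odds ratios by race/ethnicity and age
group with binary logistic regression (Wald 95% confidence intervals on
the log-odds scale).

Outcome definitions (baseline 2019; year presence only, dates ignored):

* annual return    — any encounter in 2020;
* biennial return  — an encounter in 2021 but none in 2020;
* triennial return — an encounter in 2022 but none in 2020 or 2021;
* any return       — any encounter in 2020-2022.

For the race/ethnicity analysis the sparse race levels (NH American
Indian or Alaska Native, NH Other Pacific Islander, NH Other, NH Two or
more, Missing) are dropped; the age-group analysis retains them. All
cohort women stay in every outcome model (outcome 0 when the defining
years lack encounters).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import MISSING, RACE_ANALYSIS_LEVELS, IncomeLookup, add_age_columns, assign_income_quartile
from .synthetic_data import add_outcomes

logger = logging.getLogger(__name__)

REFERENCE_LEVELS = {
    "race_ethnicity": "NH White",
    "age_group": "50-59",
    "income_quartile": "Q1",
}

ADJUSTMENT_SETS = {
    "race_ethnicity": ["age_group", "income_quartile"],
    "age_group": ["income_quartile"],
}

SENSITIVITY_2018_START = pd.Timestamp("2018-06-02")

RACE_DROP_LEVELS = [
    "NH American Indian or Alaska Native",
    "NH Other Pacific Islander",
    "NH Other",
    "NH Two or more",
    MISSING,
]


def build_cohort(
    records: pd.DataFrame,
    baseline_year: int = 2019,
    analysis: str = "age_group",
    income_lookup: IncomeLookup | None = None,
) -> pd.DataFrame:
    """One row per woman with a baseline-year encounter, plus return outcomes.

    ``records`` must at least carry the encounter-table columns; age and
    income quartile are derived here if absent (``income_lookup`` required
    for the latter unless an ``income_quartile`` column exists). Women are
    included if they have any baseline-year encounter at age >= 40 (from
    2018-06-02 when the baseline is 2018); covariates come from the FIRST
    baseline-year encounter. For ``analysis="race_ethnicity"`` the sparse
    race levels are dropped. Baseline 2018 defines only the annual
    (return-in-2019) outcome.
    """
    if baseline_year not in (2018, 2019):
        raise ValueError("baseline_year must be 2018 or 2019")
    if analysis not in ("race_ethnicity", "age_group"):
        raise ValueError("analysis must be 'race_ethnicity' or 'age_group'")
    df = records.copy()
    df["encounter_date"] = pd.to_datetime(df["encounter_date"])
    if "age" not in df.columns or "age_group" not in df.columns:
        df = add_age_columns(df)
    if "income_quartile" not in df.columns:
        if income_lookup is None:
            raise ValueError("income_quartile column absent and no income_lookup given")
        df = assign_income_quartile(df, income_lookup)
    df = df[df["age"] >= 40]

    year = df["encounter_date"].dt.year
    in_baseline = year == baseline_year
    if baseline_year == 2018:
        in_baseline &= df["encounter_date"] >= SENSITIVITY_2018_START
    base = (
        df[in_baseline]
        .sort_values(["patient_id", "encounter_date"], kind="mergesort")
        .drop_duplicates("patient_id", keep="first")
        .set_index("patient_id")
    )
    if analysis == "race_ethnicity":
        n_before = len(base)
        base = base[~base["race_ethnicity"].isin(RACE_DROP_LEVELS)]
        logger.info(
            "race analysis: dropped %d women in excluded race levels", n_before - len(base)
        )

    followup_years = (2019,) if baseline_year == 2018 else (2020, 2021, 2022)
    presence = {}
    for yr in followup_years:
        ids = set(df.loc[year == yr, "patient_id"])
        presence[yr] = base.index.to_series().isin(ids).astype(int)

    cohort = pd.DataFrame({
        "patient_id": base.index,
        "baseline_year": baseline_year,
        "race_ethnicity": base["race_ethnicity"].to_numpy(),
        "age_group": base["age_group"].to_numpy(),
        "income_quartile": base["income_quartile"].to_numpy(),
    }).reset_index(drop=True)
    if baseline_year == 2018:
        cohort["annual_return"] = presence[2019].to_numpy()
    else:
        for yr in followup_years:
            cohort[f"enc_{yr}"] = presence[yr].to_numpy()
        cohort = add_outcomes(cohort)
    return cohort


class SeparationError(RuntimeError):
    """Complete separation: an exposure cell has a constant outcome."""


def _dummies(values: pd.Series, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = [reference] + sorted(set(values) - {reference})
    mat = np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])
    return mat, levels


def fit_logistic(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    adjustment: list[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Adjusted odds ratios of ``outcome`` for each ``exposure`` level.

    Maximum-likelihood logistic regression with treatment coding; the
    returned table has one row per exposure level (reference row carries
    OR exactly 1) with Wald 95% confidence intervals
    ``exp(coef +/- 1.96 se)``. Rows with missing income quartile are
    dropped from model fitting.
    """
    if adjustment is None:
        adjustment = ADJUSTMENT_SETS.get(exposure, [])
    if reference is None:
        reference = REFERENCE_LEVELS[exposure]
    data = cohort.copy()
    for col in [exposure, *adjustment]:
        data = data[data[col] != MISSING]
    y = data[outcome].to_numpy(float)
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} is constant; cannot fit")
    cells = data.groupby(exposure, observed=True)[outcome].agg(["mean", "size"])
    degenerate = cells[(cells["mean"] == 0.0) | (cells["mean"] == 1.0)]
    if len(degenerate):
        raise SeparationError(
            f"outcome {outcome!r} is constant within {exposure} cell(s): "
            f"{list(degenerate.index)}"
        )

    X_parts, names = [np.ones((len(data), 1))], ["Intercept"]
    exp_mat, exp_levels = _dummies(data[exposure], reference)
    X_parts.append(exp_mat)
    names += [f"{exposure}[{lv}]" for lv in exp_levels[1:]]
    for col in adjustment:
        mat, levels = _dummies(data[col], REFERENCE_LEVELS.get(col, sorted(set(data[col]))[0]))
        X_parts.append(mat)
        names += [f"{col}[{lv}]" for lv in levels[1:]]
    X = np.hstack(X_parts)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    coefs = pd.Series(res.params, index=names)
    ses = pd.Series(res.bse, index=names)

    rows = [{
        "outcome": outcome, "exposure": exposure, "level": reference,
        "reference": True, "odds_ratio": 1.0, "ci_lo": np.nan, "ci_hi": np.nan,
        "n": int((data[exposure] == reference).sum()),
    }]
    for lv in exp_levels[1:]:
        b = coefs[f"{exposure}[{lv}]"]
        se = ses[f"{exposure}[{lv}]"]
        rows.append({
            "outcome": outcome, "exposure": exposure, "level": lv,
            "reference": False, "odds_ratio": float(np.exp(b)),
            "ci_lo": float(np.exp(b - 1.96 * se)),
            "ci_hi": float(np.exp(b + 1.96 * se)),
            "n": int((data[exposure] == lv).sum()),
        })
    return pd.DataFrame(rows)


def run_main_analysis(
    records: pd.DataFrame, income_lookup: IncomeLookup | None = None
) -> pd.DataFrame:
    """Table-style summary: both exposures x the four 2019-baseline outcomes."""
    outcomes = ["annual_return", "biennial_return", "triennial_return", "any_return"]
    frames = []
    for exposure in ("race_ethnicity", "age_group"):
        cohort = build_cohort(records, 2019, analysis=exposure, income_lookup=income_lookup)
        for outcome in outcomes:
            frames.append(fit_logistic(cohort, exposure, outcome))
    return pd.concat(frames, ignore_index=True)


def run_sensitivity_2018(
    records: pd.DataFrame, income_lookup: IncomeLookup | None = None
) -> pd.DataFrame:
    """Pre-pandemic check: odds of a 2019 return among women screened in 2018.

    Uses 2018 covariates (age group at the first 2018 encounter) and the
    same adjustment sets as the main analysis.
    """
    frames = []
    for exposure in ("race_ethnicity", "age_group"):
        cohort = build_cohort(records, 2018, analysis=exposure, income_lookup=income_lookup)
        frames.append(fit_logistic(cohort, exposure, "annual_return"))
    out = pd.concat(frames, ignore_index=True)
    out["outcome"] = "annual_return_2019"
    return out
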