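"""attrition_pipeline: outcome definitions, cohort filters, logistic fits."""

import numpy as np
import pandas as pd
import pytest

from screengap import synthetic_data as sd
from screengap.attrition_pipeline import (
    RACE_DROP_LEVELS,
    SeparationError,
    build_cohort,
    fit_logistic,
    run_sensitivity_2018,
)
from screengap.data_io import add_age_columns


class TestBuildCohort:
    def test_outcome_definitions_from_hand_records(self, toy_records):
        cohort = build_cohort(toy_records, 2019, analysis="age_group").set_index("patient_id")
        # year-only rule: 1-1-2019 baseline with a 12-31-2020 return is annual
        assert cohort.loc["p1", "annual_return"] == 1
        assert cohort.loc["p2", ["annual_return", "biennial_return",
                                 "triennial_return", "any_return"]].sum() == 0
        assert cohort.loc["p3", "annual_return"] == 0
        assert cohort.loc["p3", "biennial_return"] == 1
        assert cohort.loc["p3", "triennial_return"] == 0
        assert cohort.loc["p3", "any_return"] == 1
        assert cohort.loc["p4", "triennial_return"] == 1
        assert cohort.loc["p5", "annual_return"] == 1
        assert cohort.loc["p5", "biennial_return"] == 0
        # under-40 woman excluded
        assert "p6" not in cohort.index

    def test_outcomes_partition_each_woman(self, toy_records):
        cohort = build_cohort(toy_records, 2019, analysis="age_group")
        marks = (cohort["annual_return"] + cohort["biennial_return"]
                 + cohort["triennial_return"] + (1 - cohort["any_return"]))
        assert (marks == 1).all()

    def test_race_analysis_drops_sparse_levels_exact_arithmetic(self):
        # fixture mirroring the study-condition age-cohort race distribution:
        # dropping the five excluded levels must leave exactly 79,257 women
        counts = {
            "NH White": 58_091,
            "NH Black or African-American": 18_207,
            "NH Asian": 1_629,
            "NH American Indian or Alaska Native": 91,
            "NH Other Pacific Islander": 65,
            "NH Other": 120,
            "NH Two or more": 180,
            "Hispanic": 1_330,
            "Missing": 270,
        }
        n = sum(counts.values())
        assert n == 79_983
        races = np.repeat(list(counts), list(counts.values()))
        records = pd.DataFrame({
            "patient_id": [f"w{i}" for i in range(n)],
            "encounter_date": pd.Timestamp("2019-06-01"),
            "birth_date": pd.Timestamp("1960-01-01"),
            "race_ethnicity": races,
            "marital_status": "Married",
            "zip": "0", "state": "MO", "income_quartile": "Q1",
        })
        age_cohort = build_cohort(records, 2019, analysis="age_group")
        race_cohort = build_cohort(records, 2019, analysis="race_ethnicity")
        assert len(age_cohort) == 79_983
        assert len(race_cohort) == 79_257
        assert not set(race_cohort["race_ethnicity"]) & set(RACE_DROP_LEVELS)

    def test_covariates_from_first_baseline_encounter(self):
        records = pd.DataFrame({
            "patient_id": ["w", "w"],
            "encounter_date": pd.to_datetime(["2019-08-01", "2019-02-01"]),
            "birth_date": pd.Timestamp("1969-05-01"),
            "race_ethnicity": "NH White", "marital_status": "Married",
            "zip": "0", "state": "MO",
            "income_quartile": ["Q3", "Q2"],
        })
        cohort = build_cohort(records, 2019, analysis="age_group")
        assert cohort.iloc[0]["income_quartile"] == "Q2"  # earliest encounter wins
        assert cohort.iloc[0]["age_group"] == "40-49"  # age 49 at the Feb encounter

    def test_invalid_baseline_year_rejected(self, toy_records):
        with pytest.raises(ValueError):
            build_cohort(toy_records, 2020, analysis="age_group")


class TestFitLogistic:
    def test_saturated_2x2_matches_cross_product_ratio(self):
        # exposed level: 40 returners / 10 non; reference: 20 / 30
        df = pd.DataFrame({
            "race_ethnicity": ["NH Asian"] * 50 + ["NH White"] * 50,
            "annual_return": [1] * 40 + [0] * 10 + [1] * 20 + [0] * 30,
        })
        res = fit_logistic(df, "race_ethnicity", "annual_return", adjustment=[])
        level_row = res[res["level"] == "NH Asian"].iloc[0]
        assert level_row["odds_ratio"] == pytest.approx((40 * 30) / (10 * 20), rel=1e-8)
        ref_row = res[res["reference"]].iloc[0]
        assert ref_row["odds_ratio"] == 1.0

    def test_independent_exposure_gives_null_or(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "age_group": rng.choice(["50-59", ">=80"], 40_000),
            "income_quartile": rng.choice(["Q1", "Q2"], 40_000),
            "any_return": rng.random(40_000) < 0.6,
        })
        res = fit_logistic(df, "age_group", "any_return")
        row = res[res["level"] == ">=80"].iloc[0]
        assert row["ci_lo"] < 1.0 < row["ci_hi"]
        assert abs(row["odds_ratio"] - 1.0) < 0.1

    def test_recovers_injected_conditional_or(self):
        cfg = sd.AttritionSimConfig(
            n_women=80_000, primary_outcome="any_return", p_ref=0.75,
            odds_ratios={"age_group": {">=80": 0.45}}, seed=13,
        )
        cohort = sd.simulate_attrition_cohort(cfg)
        res = fit_logistic(cohort, "age_group", "any_return")
        row = res[res["level"] == ">=80"].iloc[0]
        assert row["ci_lo"] <= 0.45 <= row["ci_hi"]
        assert abs(row["odds_ratio"] - 0.45) / 0.45 < 0.10

    def test_invariant_to_row_order_and_id_relabeling(self):
        cfg = sd.AttritionSimConfig(n_women=5000, seed=14)
        cohort = sd.simulate_attrition_cohort(cfg)
        shuffled = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["patient_id"] = [f"x{i}" for i in range(len(shuffled))]
        a = fit_logistic(cohort, "age_group", "any_return")
        b = fit_logistic(shuffled, "age_group", "any_return")
        pd.testing.assert_frame_equal(a, b)

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"age_group": ["50-59", ">=80"] * 10,
                           "income_quartile": "Q1", "any_return": 1})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(df, "age_group", "any_return")

    def test_separation_names_the_cell(self):
        df = pd.DataFrame({
            "age_group": ["50-59"] * 20 + [">=80"] * 20,
            "income_quartile": "Q1",
            "any_return": [0, 1] * 10 + [1] * 20,
        })
        with pytest.raises(SeparationError, match=">=80"):
            fit_logistic(df, "age_group", "any_return")


class TestSensitivity2018:
    def _records(self):
        rows = [
            ("a", "2018-07-01"), ("a", "2019-03-01"),   # returns in 2019
            ("b", "2018-08-15"),                          # does not return
            ("c", "2018-05-01"), ("c", "2019-06-01"),    # before 6-02: excluded
            ("d", "2018-10-01"), ("d", "2019-12-31"),
            ("e", "2018-11-11"),
            ("f", "2018-06-02"), ("f", "2019-01-01"),
        ]
        df = pd.DataFrame(rows, columns=["patient_id", "encounter_date"])
        df["encounter_date"] = pd.to_datetime(df["encounter_date"])
        df["birth_date"] = pd.Timestamp("1958-03-03")
        df["race_ethnicity"] = np.where(df["patient_id"].isin(["a", "d"]),
                                        "NH Asian", "NH White")
        df["marital_status"] = "Single"
        df["zip"] = "0"
        df["state"] = "MO"
        df["income_quartile"] = np.where(df["patient_id"].isin(["b", "f"]), "Q2", "Q1")
        return df

    def test_2018_window_rule_and_annual_outcome(self):
        cohort = build_cohort(self._records(), 2018, analysis="age_group")
        idx = cohort.set_index("patient_id")
        assert "c" not in idx.index  # screened before 6-02-2018 only
        assert idx.loc["a", "annual_return"] == 1
        assert idx.loc["b", "annual_return"] == 0
        assert idx.loc["f", "annual_return"] == 1

    def test_null_generator_gives_near_unit_ors(self):
        cfg = sd.AttritionSimConfig(n_women=40_000, baseline_year=2018,
                                    primary_outcome="annual_return", p_ref=0.6, seed=15)
        cohort = sd.simulate_attrition_cohort(cfg)
        enc, lookup = sd.cohort_to_encounters(cohort, seed=15)
        res = run_sensitivity_2018(enc, lookup)
        fitted = res[~res["reference"]]
        assert ((fitted["odds_ratio"] > 0.85) & (fitted["odds_ratio"] < 1.18)).all()
        assert (res["outcome"] == "annual_return_2019").all()
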