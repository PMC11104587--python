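"""Shared fixtures; the expensive MCMC fits are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from screengap import data_io as dio
from screengap import posterior_inference as pi
from screengap import synthetic_data as sd
from screengap.interruption_model import ModelSpec

GEN_SEED = 11
MCMC_SEED = 5

#: Per-group drop fractions and windows mirroring the study-condition race-level
#: estimates, with baselines proportional to the 2019 race counts scaled to
#: 800 encounters/week total.
RACE_SIM_KWARGS = dict(
    groups={
        "NH White": 585.9,
        "NH Black or African-American": 184.2,
        "NH Asian": 16.4,
        "Hispanic": 13.4,
    },
    drop_fraction={
        "NH White": 0.986,
        "NH Black or African-American": 0.996,
        "NH Asian": 0.989,
        "Hispanic": 0.991,
    },
    window_start={
        "NH White": "2020-03-22",
        "NH Black or African-American": "2020-03-22",
        "NH Asian": "2020-03-15",
        "Hispanic": "2020-03-22",
    },
    window_end={
        "NH White": "2020-05-24",
        "NH Black or African-American": "2020-05-17",
        "NH Asian": "2020-05-24",
        "Hispanic": "2020-05-24",
    },
)


@pytest.fixture(scope="session")
def calendar():
    return dio.build_holiday_calendar(2018, 2023)


@pytest.fixture(scope="session")
def overall_sim():
    """Single-group study-condition simulation: 1000/week, 98.8% drop."""
    cfg = sd.CountSimConfig(seed=GEN_SEED)
    series, truth = sd.simulate_weekly_counts(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def overall_fit(overall_sim):
    """Full-size fit of the single-group study-condition series."""
    _, series, _ = overall_sim
    fitted = pi.fit(
        series, ModelSpec(), pi.MCMCSettings(chains=4, warmup=1000, draws=1000, seed=MCMC_SEED)
    )
    cf = pi.counterfactual(fitted, seed=MCMC_SEED)
    return fitted, cf


@pytest.fixture(scope="session")
def race_sim():
    cfg = sd.CountSimConfig(seed=GEN_SEED, **RACE_SIM_KWARGS)
    series, truth = sd.simulate_weekly_counts(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def race_fit(race_sim):
    """Four-group fit at a reduced-but-adequate MCMC size."""
    _, series, _ = race_sim
    fitted = pi.fit(
        series, ModelSpec(), pi.MCMCSettings(chains=2, warmup=800, draws=800, seed=MCMC_SEED)
    )
    cf = pi.counterfactual(fitted, seed=MCMC_SEED)
    return fitted, cf


@pytest.fixture()
def toy_records():
    """Hand-written encounter rows exercising the outcome definitions."""
    rows = [
        # annual: 2019 and late-2020 return (the year-only rule)
        ("p1", "2019-01-01", "1970-05-01"),
        ("p1", "2020-12-31", "1970-05-01"),
        # no return at all
        ("p2", "2019-06-15", "1960-01-20"),
        # biennial: 2021 but not 2020
        ("p3", "2019-03-10", "1955-07-04"),
        ("p3", "2021-02-01", "1955-07-04"),
        # triennial: 2022 only
        ("p4", "2019-09-09", "1948-11-30"),
        ("p4", "2022-10-10", "1948-11-30"),
        # annual + later years too
        ("p5", "2019-05-05", "1975-02-14"),
        ("p5", "2020-05-04", "1975-02-14"),
        ("p5", "2021-05-03", "1975-02-14"),
        # under 40 at encounter: excluded
        ("p6", "2019-08-08", "1985-12-25"),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "encounter_date", "birth_date"])
    df["encounter_date"] = pd.to_datetime(df["encounter_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["race_ethnicity"] = "NH White"
    df["marital_status"] = "Married"
    df["zip"] = "63101"
    df["state"] = "MO"
    df["income_quartile"] = "Q2"
    return df
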