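"""Synthetic weekly-count series and encounter/cohort generators.

The study's EHR extract is not public, so every analysis here runs against
synthetic data with the same statistical structure and *known injected
truths*: per-group weekly encounter counts with seasonality, holiday dips,
overdispersion, and a spring-2020 interruption window with a configurable
drop fraction; and woman-level return-screening cohorts whose designated
outcome follows an exact conditional-logistic model with injected odds
ratios. Recovery of these truths by the estimation modules is the
pipeline's core correctness check.

All randomness flows from a single integer seed through named substreams,
so each generator is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import data_io
from .data_io import (
    INCOME_QUARTILES,
    IncomeLookup,
    RACE_ANALYSIS_LEVELS,
    WeeklyCounts,
    build_holiday_calendar,
    week_grid,
)
from .interruption_model import WEEKS_PER_YEAR

_STREAMS = {"weekly": 0, "encounters": 1, "cohort": 2, "zips": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# weekly count generator


@dataclass
class CountSimConfig:
    """Configuration of the weekly-count generator.

    ``groups`` maps a group label to its baseline weekly encounter rate.
    ``seasonal_amplitudes`` are log-scale harmonic coefficients ordered
    [sin1, cos1, sin2, cos2, ...] on the same annual basis the model uses.
    ``holiday_effect`` multiplies the mean in flagged weeks. Inside the
    interruption window the mean is multiplied by ``1 - w_t * drop``,
    where the window weight ``w_t`` is 1 for weeks between ``window_start``
    and ``window_end`` (Sunday labels, inclusive) and ramps linearly over
    ``ramp_weeks`` weeks outside them (0 = hard on/off). ``drop_fraction``
    and the window dates may be scalars or per-group dicts.
    """

    groups: dict = field(default_factory=lambda: {"overall": 1000.0})
    seasonal_amplitudes: tuple = (0.06, 0.08, 0.03, 0.02)
    holiday_effect: float = 0.85
    window_start: object = "2020-03-15"
    window_end: object = "2020-05-24"
    drop_fraction: object = 0.988
    ramp_weeks: float = 0.0
    overdispersion_sd: float = 0.05
    date_range: tuple = ("2019-01-06", "2021-12-26")
    mean_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for g, rate in self.groups.items():
            if rate <= 0:
                raise ValueError(f"baseline rate for group {g!r} must be > 0")
        for g in self.groups:
            d = self.drop_for(g)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"drop_fraction for {g!r} outside [0, 1]")
            ws, we = self.window_for(g)
            if ws >= we:
                raise ValueError("window_start must precede window_end")
            lo, hi = (pd.Timestamp(x) for x in self.date_range)
            if d > 0 and not (lo <= ws <= hi and lo <= we <= hi):
                raise ValueError("interruption window outside date_range")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion_sd must be >= 0")

    def _per_group(self, value, group):
        return value[group] if isinstance(value, dict) else value

    def drop_for(self, group) -> float:
        return float(self._per_group(self.drop_fraction, group))

    def window_for(self, group) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (
            pd.Timestamp(self._per_group(self.window_start, group)),
            pd.Timestamp(self._per_group(self.window_end, group)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "CountSimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CountTruth:
    """Injected parameters and noise-free expected paths of the generator."""

    config: CountSimConfig
    week_starts: pd.DatetimeIndex
    groups: list[str]
    expected_interrupted: np.ndarray  # (G, T)
    expected_counterfactual: np.ndarray  # (G, T)
    window_weight: np.ndarray  # (G, T), the generator-side 1 - tau
    true_pct_drop: dict  # group -> window-weighted percent drop

    def to_json_dict(self) -> dict:
        return {
            "drop_fraction": {g: self.config.drop_for(g) for g in self.groups},
            "window_start": {g: str(self.config.window_for(g)[0].date()) for g in self.groups},
            "window_end": {g: str(self.config.window_for(g)[1].date()) for g in self.groups},
            "true_pct_drop": self.true_pct_drop,
            "overdispersion_sd": self.config.overdispersion_sd,
            "holiday_effect": self.config.holiday_effect,
            "seed": self.config.seed,
        }


def _window_weight(grid: pd.DatetimeIndex, ws, we, ramp_weeks: float) -> np.ndarray:
    """Generator-side interruption weight: 1 inside [ws, we], linear ramps."""
    t = grid.to_numpy()
    dw_before = (np.datetime64(ws) - t) / np.timedelta64(7, "D")  # >0 before window
    dw_after = (t - np.datetime64(we)) / np.timedelta64(7, "D")
    w = np.ones(len(grid))
    if ramp_weeks > 0:
        w = np.minimum(1.0 - dw_before / ramp_weeks, 1.0 - dw_after / ramp_weeks)
        w = np.clip(w, 0.0, 1.0)
    else:
        w = ((dw_before <= 0) & (dw_after <= 0)).astype(float)
    return w


def simulate_weekly_counts(cfg: CountSimConfig) -> tuple[WeeklyCounts, CountTruth]:
    """Draw per-group weekly counts from the generating process.

    Counts are Poisson with log-mean ``log(baseline) + harmonics +
    holiday + log(1 - w_t * drop) + Normal(0, overdispersion_sd)``; the
    suppressed mean is floored at ``mean_floor`` encounters/week so a full
    stop (drop = 1) stays on the log scale. Identical seeds give identical
    output.
    """
    grid = week_grid(*cfg.date_range)
    T = len(grid)
    groups = list(cfg.groups)
    calendar = build_holiday_calendar(grid[0].year, grid[-1].year)
    hol = calendar.indicator(grid)
    w_idx = np.arange(T, dtype=float)
    seasonal = np.zeros(T)
    for j, amp in enumerate(cfg.seasonal_amplitudes):
        k = j // 2 + 1
        ang = 2.0 * np.pi * k * w_idx / WEEKS_PER_YEAR
        seasonal += amp * (np.sin(ang) if j % 2 == 0 else np.cos(ang))

    rng = _rng(cfg.seed, "weekly")
    counts = np.empty((len(groups), T), dtype=int)
    e_int = np.empty((len(groups), T))
    e_cf = np.empty((len(groups), T))
    weight = np.empty((len(groups), T))
    true_pct = {}
    for i, g in enumerate(groups):
        ws, we = cfg.window_for(g)
        w = _window_weight(grid, ws, we, cfg.ramp_weeks)
        base = cfg.groups[g] * np.exp(seasonal) * cfg.holiday_effect ** hol
        suppressed = np.maximum(base * (1.0 - w * cfg.drop_for(g)), cfg.mean_floor)
        noise = np.exp(rng.normal(0.0, cfg.overdispersion_sd, size=T))
        counts[i] = rng.poisson(suppressed * noise)
        e_int[i], e_cf[i], weight[i] = suppressed, base, w
        denom = float(np.sum(w * base))
        true_pct[g] = 100.0 * float(np.sum(w * (base - suppressed))) / denom if denom else 0.0

    series = WeeklyCounts(groups, grid, counts)
    truth = CountTruth(cfg, grid, groups, e_int, e_cf, weight, true_pct)
    return series, truth


# ---------------------------------------------------------------------------
# encounter-level generator


@dataclass
class Demography:
    """Covariate mixes for synthetic encounter records (study-like defaults)."""

    age_mix: dict = field(default_factory=lambda: {
        "40-49": 0.213, "50-59": 0.280, "60-69": 0.306, "70-79": 0.167, ">=80": 0.034,
    })
    marital_mix: dict = field(default_factory=lambda: {
        "Married": 0.593, "Single": 0.405, "Unknown": 0.002,
    })
    state_mix: dict = field(default_factory=lambda: {"MO": 0.713, "IL": 0.287})

    def __post_init__(self):
        for name in ("age_mix", "marital_mix", "state_mix"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} proportions must sum to 1 (got {total})")


_AGE_RANGE = {"40-49": (40, 49), "50-59": (50, 59), "60-69": (60, 69),
              "70-79": (70, 79), ">=80": (80, 94)}


def _birth_date_for(encounter: pd.Timestamp, age_years: int, rng) -> pd.Timestamp:
    # subtracting whole years then 0..360 extra days keeps completed age exact
    back_days = int(round(age_years * 365.2425)) + int(rng.integers(0, 360))
    return encounter - pd.Timedelta(days=back_days)


def simulate_encounter_table(
    cfg: CountSimConfig,
    demography: Demography | None = None,
    income_lookup: IncomeLookup | None = None,
) -> pd.DataFrame:
    """Individual encounter records whose weekly bins match a count draw.

    Draws a weekly series with ``simulate_weekly_counts`` and expands each
    group-week count into that many records: encounter dates uniform within
    the week, race/ethnicity equal to the series group when group labels
    are race levels (otherwise covariates all sampled from the demography
    mix), ages >= 40 consistent with the sampled age band.
    """
    demography = demography if demography is not None else Demography()
    if income_lookup is None:
        income_lookup = synthetic_income_lookup(seed=cfg.seed)
    series, _ = simulate_weekly_counts(cfg)
    rng = _rng(cfg.seed, "encounters")
    race_groups = all(g in data_io.RACE_LEVELS for g in series.groups)
    zips = income_lookup.table["zip"].to_numpy()

    age_labels = list(demography.age_mix)
    age_probs = np.array(list(demography.age_mix.values()))
    marital_labels = list(demography.marital_mix)
    marital_probs = np.array(list(demography.marital_mix.values()))
    state_labels = list(demography.state_mix)
    state_probs = np.array(list(demography.state_mix.values()))

    rows = []
    pid = 0
    for i, g in enumerate(series.groups):
        for t, wk in enumerate(series.week_starts):
            n = int(series.counts[i, t])
            if n == 0:
                continue
            days = rng.integers(0, 7, size=n)
            for d in days:
                enc = wk + pd.Timedelta(days=int(d))
                band = age_labels[rng.choice(len(age_labels), p=age_probs)]
                lo, hi = _AGE_RANGE[band]
                age = int(rng.integers(lo, hi + 1))
                rows.append({
                    "patient_id": f"W{pid:07d}",
                    "encounter_date": enc,
                    "birth_date": _birth_date_for(enc, age, rng),
                    "race_ethnicity": g if race_groups else rng.choice(RACE_ANALYSIS_LEVELS),
                    "marital_status": marital_labels[rng.choice(len(marital_labels), p=marital_probs)],
                    "zip": str(rng.choice(zips)),
                    "state": state_labels[rng.choice(len(state_labels), p=state_probs)],
                })
                pid += 1
    return pd.DataFrame(rows)


def synthetic_income_lookup(n_zips: int = 40, seed: int = 0) -> IncomeLookup:
    """A synthetic catchment zip list with distinct incomes (quartiles exact)."""
    rng = _rng(seed, "zips")
    zips = [f"6{z:04d}" for z in rng.choice(9999, size=n_zips, replace=False)]
    incomes = np.sort(rng.uniform(25_000, 120_000, size=n_zips)).round(0)
    return IncomeLookup.from_incomes(
        pd.DataFrame({"zip": zips, "median_household_income": incomes})
    )


# ---------------------------------------------------------------------------
# attrition cohort generator

OUTCOMES = ["annual_return", "biennial_return", "triennial_return", "any_return"]


@dataclass
class AttritionSimConfig:
    """Configuration of the return-screening cohort generator.

    One outcome (``primary_outcome``) is generated with an exact
    conditional-logistic law: its logit is ``logit(p_ref)`` plus the log
    odds ratios of the woman's non-reference race, age, and income levels.
    The remaining calendar-year encounter pattern is filled in with
    covariate-free allocation rates so the four return outcomes keep their
    mutually exclusive structure. Proportions must each sum to 1; odds
    ratios are per exposure level with the reference level omitted
    (NH White, 50-59, Q1).
    """

    n_women: int = 80_000
    baseline_year: int = 2019
    race_mix: dict = field(default_factory=lambda: {
        "NH White": 0.733, "NH Black or African-American": 0.230,
        "NH Asian": 0.020, "Hispanic": 0.017,
    })
    age_mix: dict = field(default_factory=lambda: {
        "40-49": 0.215, "50-59": 0.280, "60-69": 0.305, "70-79": 0.166, ">=80": 0.034,
    })
    income_mix: dict = field(default_factory=lambda: dict.fromkeys(INCOME_QUARTILES, 0.25))
    primary_outcome: str = "any_return"
    p_ref: float = 0.75
    odds_ratios: dict = field(default_factory=dict)  # axis -> level -> OR
    allocation: dict = field(default_factory=lambda: {
        "annual_given_any": 0.75, "biennial_given_rest": 0.60,
        "p2021_given_2020": 0.6, "p2022_given_2020_2021": 0.6,
    })
    seed: int = 0

    def __post_init__(self):
        if self.baseline_year not in (2018, 2019):
            raise ValueError("baseline_year must be 2018 or 2019")
        if self.primary_outcome not in OUTCOMES:
            raise ValueError(f"primary_outcome must be one of {OUTCOMES}")
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must be in (0, 1)")
        for name in ("race_mix", "age_mix", "income_mix"):
            if abs(sum(getattr(self, name).values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        for axis, table in self.odds_ratios.items():
            for level, ratio in table.items():
                if ratio <= 0:
                    raise ValueError(f"odds ratio for {axis}={level!r} must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "AttritionSimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _linear_predictor(cfg: AttritionSimConfig, race, age, income) -> np.ndarray:
    lp = np.full(len(race), logit(cfg.p_ref))
    for axis, values in (("race_ethnicity", race), ("age_group", age), ("income_quartile", income)):
        table = cfg.odds_ratios.get(axis, {})
        for level, ratio in table.items():
            lp = lp + np.log(ratio) * (values == level)
    return lp


def simulate_attrition_cohort(cfg: AttritionSimConfig) -> pd.DataFrame:
    """One row per woman with covariates, year-presence flags, and outcomes.

    The primary outcome follows its injected logistic law exactly; the
    year pattern (2020/2021/2022 encounter presence) is completed around
    it so that annual/biennial/triennial/any keep their defining partition
    structure. Identical seeds give identical tables.
    """
    rng = _rng(cfg.seed, "cohort")
    n = cfg.n_women
    race = rng.choice(list(cfg.race_mix), p=list(cfg.race_mix.values()), size=n)
    age = rng.choice(list(cfg.age_mix), p=list(cfg.age_mix.values()), size=n)
    income = rng.choice(list(cfg.income_mix), p=list(cfg.income_mix.values()), size=n)
    p_primary = expit(_linear_predictor(cfg, race, age, income))
    z = rng.random(n) < p_primary
    alloc = cfg.allocation

    y20 = np.zeros(n, dtype=bool)
    y21 = np.zeros(n, dtype=bool)
    y22 = np.zeros(n, dtype=bool)
    if cfg.primary_outcome == "annual_return":
        y20 = z.copy()
        rest = ~z
        y21[rest] = rng.random(rest.sum()) < alloc["biennial_given_rest"]
        later = rest & ~y21
        y22[later] = rng.random(later.sum()) < alloc["p2022_given_2020_2021"]
    elif cfg.primary_outcome == "biennial_return":
        y21 = z.copy()  # 2021 yes, 2020 no
        rest = ~z
        y20[rest] = rng.random(rest.sum()) < alloc["annual_given_any"]
        with20 = rest & y20
        y21[with20] = rng.random(with20.sum()) < alloc["p2021_given_2020"]
        none_yet = rest & ~y20
        y22[none_yet] = rng.random(none_yet.sum()) < alloc["p2022_given_2020_2021"]
        y22[with20] = rng.random(with20.sum()) < alloc["p2022_given_2020_2021"]
    elif cfg.primary_outcome == "triennial_return":
        y22 = z.copy()  # 2022 only
        rest = ~z
        y20[rest] = rng.random(rest.sum()) < alloc["annual_given_any"]
        y21[rest & y20] = rng.random((rest & y20).sum()) < alloc["p2021_given_2020"]
        y21[rest & ~y20] = rng.random((rest & ~y20).sum()) < alloc["biennial_given_rest"]
        y22[rest & y20] = rng.random((rest & y20).sum()) < alloc["p2022_given_2020_2021"]
    else:  # any_return
        y20[z] = rng.random(z.sum()) < alloc["annual_given_any"]
        no20 = z & ~y20
        y21[no20] = rng.random(no20.sum()) < alloc["biennial_given_rest"]
        y22[z & ~y20 & ~y21] = True  # any=1 must have some pandemic-year encounter
        y21[z & y20] = rng.random((z & y20).sum()) < alloc["p2021_given_2020"]
        y22[z & y20] = rng.random((z & y20).sum()) < alloc["p2022_given_2020_2021"]

    cohort = pd.DataFrame({
        "patient_id": [f"A{i:07d}" for i in range(n)],
        "baseline_year": cfg.baseline_year,
        "race_ethnicity": race,
        "age_group": age,
        "income_quartile": income,
        "enc_2020": y20.astype(int),
        "enc_2021": y21.astype(int),
        "enc_2022": y22.astype(int),
    })
    return add_outcomes(cohort)


def add_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the four return outcomes from calendar-year presence flags."""
    out = cohort.copy()
    y20, y21, y22 = (out[f"enc_{y}"].astype(bool) for y in (2020, 2021, 2022))
    out["annual_return"] = y20.astype(int)
    out["biennial_return"] = (y21 & ~y20).astype(int)
    out["triennial_return"] = (y22 & ~y21 & ~y20).astype(int)
    out["any_return"] = (y20 | y21 | y22).astype(int)
    return out


def cohort_to_encounters(
    cohort: pd.DataFrame,
    seed: int = 0,
    income_lookup: IncomeLookup | None = None,
) -> tuple[pd.DataFrame, IncomeLookup]:
    """Expand a cohort table into encounter-level records.

    Each woman gets one baseline-year encounter (uniform date) plus one
    encounter in every pandemic year her presence flags mark; birth dates
    are consistent with her age band at the baseline encounter and her zip
    is drawn from her income quartile's zips in the lookup.
    """
    rng = _rng(seed, "encounters")
    if income_lookup is None:
        income_lookup = synthetic_income_lookup(seed=seed)
    by_quartile = {
        q: income_lookup.table.loc[income_lookup.table["income_quartile"] == q, "zip"].to_numpy()
        for q in INCOME_QUARTILES
    }
    rows = []
    for rec in cohort.itertuples(index=False):
        year = int(rec.baseline_year)
        base = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(rng.integers(0, 365)))
        if year == 2018 and base < pd.Timestamp("2018-06-02"):
            base = pd.Timestamp("2018-06-02") + pd.Timedelta(days=int(rng.integers(0, 200)))
        lo, hi = _AGE_RANGE[rec.age_group]
        age = int(rng.integers(lo, hi + 1))
        birth = _birth_date_for(base, age, rng)
        zips = by_quartile.get(rec.income_quartile)
        zipc = str(rng.choice(zips)) if zips is not None and len(zips) else "00000"
        dates = [base]
        for yr, flag in ((2020, rec.enc_2020), (2021, rec.enc_2021), (2022, rec.enc_2022)):
            if year == 2018:
                yr -= 1  # sensitivity design: returns are observed in 2019
                if yr != 2019 or not flag:
                    continue
            if flag:
                dates.append(pd.Timestamp(f"{yr}-01-01") + pd.Timedelta(days=int(rng.integers(0, 365))))
        for dt in dates:
            rows.append({
                "patient_id": rec.patient_id,
                "encounter_date": dt,
                "birth_date": birth,
                "race_ethnicity": rec.race_ethnicity,
                "marital_status": "Married",
                "zip": zipc,
                "state": "MO",
            })
    return pd.DataFrame(rows), income_lookup
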