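"""Reading encounter-level screening records and shaping them for analysis.

The analyses downstream operate on two shapes of data:

* an encounter table — one row per screening-mammogram encounter, with the
  woman's identifier, encounter and birth dates, race/ethnicity, marital
  status, and residence zip/state;
* weekly count series — per-group encounter counts on a common, contiguous
  Sunday-start week grid.

This module reads and validates the encounter CSV, derives per-encounter
covariates (age at encounter, catchment-area income quartile), bins
encounters into Sunday-start weeks, and builds the holiday calendar used as
a regression indicator by the count model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENCOUNTER_COLUMNS = [
    "patient_id",
    "encounter_date",
    "birth_date",
    "race_ethnicity",
    "marital_status",
    "zip",
    "state",
]

RACE_LEVELS = [
    "NH White",
    "NH Black or African-American",
    "NH Asian",
    "NH American Indian or Alaska Native",
    "NH Other Pacific Islander",
    "NH Other",
    "NH Two or more",
    "Hispanic",
    "Missing",
]

#: The four race/ethnicity levels carried into the race-stratified analyses.
RACE_ANALYSIS_LEVELS = [
    "NH White",
    "NH Black or African-American",
    "NH Asian",
    "Hispanic",
]

AGE_GROUP_LABELS = ["40-49", "50-59", "60-69", "70-79", ">=80"]

_AGE_BREAKS = [40, 50, 60, 70, 80]

MISSING = "Missing"


class SchemaError(ValueError):
    """An input table does not have the expected columns."""


# ---------------------------------------------------------------------------
# encounter table I/O


def read_encounters(path) -> pd.DataFrame:
    """Read an encounter CSV into a validated DataFrame.

    The file must have a header naming ``patient_id, encounter_date,
    birth_date, race_ethnicity, marital_status, zip, state``; dates are
    ISO-8601. Unknown categorical values are kept verbatim (and logged);
    filtering to the analysis population happens downstream.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValueError
        if a date fails to parse; the message names the offending row index.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "zip": str}, keep_default_na=False)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"encounter file missing required column(s): {missing}")
    df = df[ENCOUNTER_COLUMNS].copy()
    for col in ("encounter_date", "birth_date"):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].astype(str).str.len().gt(0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unparseable date {df[col].iloc[row]!r} in column {col}, row {row}"
            )
        df[col] = parsed
    df.loc[df["zip"] == "", "zip"] = MISSING
    df.loc[df["race_ethnicity"] == "", "race_ethnicity"] = MISSING
    unknown = set(df["race_ethnicity"]) - set(RACE_LEVELS)
    if unknown:
        logger.warning("unrecognized race/ethnicity values kept verbatim: %s", sorted(unknown))
    return df


def write_encounters(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("encounter_date", "birth_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out[ENCOUNTER_COLUMNS].to_csv(path, index=False)


def dedupe_same_day(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse to one encounter per woman per calendar date.

    Screening encounters are daily-unique events; exact same-day duplicates
    are administrative artifacts. The number collapsed is logged.
    """
    before = len(df)
    out = df.drop_duplicates(subset=["patient_id", "encounter_date"], keep="first")
    dropped = before - len(out)
    if dropped:
        logger.info("collapsed %d duplicate same-day encounters", dropped)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# derived covariates


def compute_age(birth_date, encounter_date) -> int:
    """Completed years between birth and encounter."""
    b, e = pd.Timestamp(birth_date), pd.Timestamp(encounter_date)
    if e < b:
        raise ValueError(f"encounter date {e.date()} precedes birth date {b.date()}")
    return e.year - b.year - ((e.month, e.day) < (b.month, b.day))


def age_group(age) -> str:
    """Map an age in years to the analysis age band (ages < 40 get NaN)."""
    idx = np.searchsorted(_AGE_BREAKS, np.asarray(age), side="right") - 1
    labels = np.array(AGE_GROUP_LABELS, dtype=object)
    out = np.where(idx >= 0, labels[np.clip(idx, 0, len(labels) - 1)], None)
    return out.item() if np.isscalar(age) or np.ndim(age) == 0 else out


def add_age_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ``age`` (completed years at encounter) and ``age_group``."""
    b = pd.to_datetime(df["birth_date"])
    e = pd.to_datetime(df["encounter_date"])
    if (e < b).any():
        row = int(np.flatnonzero((e < b).to_numpy())[0])
        raise ValueError(f"encounter precedes birth at row {row}")
    age = e.dt.year - b.dt.year - (
        (e.dt.month * 100 + e.dt.day) < (b.dt.month * 100 + b.dt.day)
    ).astype(int)
    out = df.copy()
    out["age"] = age
    out["age_group"] = age_group(age.to_numpy())
    return out


# ---------------------------------------------------------------------------
# week grid


def assign_week(d) -> pd.Timestamp:
    """The Sunday on or before ``d`` (weeks are labeled by their Sunday start)."""
    ts = pd.Timestamp(d)
    return ts - pd.Timedelta(days=(ts.dayofweek + 1) % 7)


def week_grid(start, end) -> pd.DatetimeIndex:
    """Contiguous Sunday week-start labels covering [start, end]."""
    lo, hi = assign_week(start), assign_week(end)
    if hi < lo:
        raise ValueError("empty date range")
    return pd.date_range(lo, hi, freq="7D")


@dataclass
class WeeklyCounts:
    """Per-group weekly encounter counts on a shared Sunday-start grid.

    ``counts`` is a (groups x weeks) integer array; ``week_starts`` are the
    Sunday labels of the contiguous grid.
    """

    groups: list[str]
    week_starts: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.groups), len(self.week_starts)):
            raise ValueError("counts shape does not match groups x weeks")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        deltas = np.diff(self.week_starts.to_numpy()).astype("timedelta64[D]")
        if len(deltas) and not (deltas == np.timedelta64(7, "D")).all():
            raise ValueError("week grid not contiguous with 7-day spacing")

    @property
    def n_weeks(self) -> int:
        return len(self.week_starts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format ``group, week_start, count`` table."""
        return pd.DataFrame(
            {
                "group": np.repeat(self.groups, self.n_weeks),
                "week_start": np.tile(self.week_starts, len(self.groups)),
                "count": self.counts.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["week_start"] = df["week_start"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeeklyCounts":
        df = df.copy()
        df["week_start"] = pd.to_datetime(df["week_start"])
        wide = df.pivot_table(
            index="group", columns="week_start", values="count", aggfunc="sum", fill_value=0
        ).sort_index(axis=1)
        grid = week_grid(wide.columns[0], wide.columns[-1])
        wide = wide.reindex(columns=grid, fill_value=0)
        return cls(list(wide.index), grid, wide.to_numpy(dtype=int))

    @classmethod
    def from_csv(cls, path) -> "WeeklyCounts":
        return cls.from_frame(pd.read_csv(path))


def weekly_counts(df: pd.DataFrame, grouping: str, date_range) -> WeeklyCounts:
    """Bin encounters into Sunday-start weekly counts, per group.

    ``grouping`` is one of ``"none"`` (a single overall series),
    ``"race_ethnicity"``, or ``"age_group"``. The caller is responsible for
    restricting to the analysis population first (age >= 40; for race
    grouping, the four analyzed levels). Every returned series lives on the
    identical contiguous grid covering ``date_range``; weeks with no
    encounters carry count 0.
    """
    start, end = date_range
    grid = week_grid(start, end)
    if grouping == "none":
        key = pd.Series("overall", index=df.index)
    elif grouping in ("race_ethnicity", "age_group"):
        key = df[grouping]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    weeks = pd.to_datetime(df["encounter_date"]).map(assign_week)
    in_range = (weeks >= grid[0]) & (weeks <= grid[-1])
    tab = (
        pd.DataFrame({"group": key[in_range], "week": weeks[in_range]})
        .groupby(["group", "week"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=grid, fill_value=0)
    )
    if grouping == "none" and tab.empty:
        tab = pd.DataFrame(0, index=["overall"], columns=grid)
    return WeeklyCounts(list(tab.index), grid, tab.to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# holiday calendar

_FIXED_HOLIDAYS = [("New Year's Day", 1, 1), ("Independence Day", 7, 4), ("Christmas Day", 12, 25)]


def _last_monday_of_may(year: int) -> date:
    d = date(year, 5, 31)
    return d - timedelta(days=d.weekday())


def _first_monday_of_september(year: int) -> date:
    d = date(year, 9, 1)
    return d + timedelta(days=(7 - d.weekday()) % 7)


def _fourth_thursday_of_november(year: int) -> date:
    d = date(year, 11, 1)
    first_thu = d + timedelta(days=(3 - d.weekday()) % 7)
    return first_thu + timedelta(weeks=3)


def holiday_dates(year: int) -> dict[str, date]:
    """The six federal holidays the count model adjusts for, by statutory rule."""
    out = {name: date(year, m, d) for name, m, d in _FIXED_HOLIDAYS}
    out["Memorial Day"] = _last_monday_of_may(year)
    out["Labor Day"] = _first_monday_of_september(year)
    out["Thanksgiving Day"] = _fourth_thursday_of_november(year)
    return out


@dataclass
class HolidayCalendar:
    """Weeks (Sunday labels) containing at least one of the six holidays."""

    flagged_weeks: set = field(default_factory=set)
    holidays: dict = field(default_factory=dict)

    def is_flagged(self, week_start) -> bool:
        return pd.Timestamp(week_start) in self.flagged_weeks

    def indicator(self, week_starts) -> np.ndarray:
        """0/1 holiday indicator aligned with ``week_starts``."""
        return np.array([1.0 if self.is_flagged(w) else 0.0 for w in week_starts])


def build_holiday_calendar(first_year: int, last_year: int) -> HolidayCalendar:
    """Flag each week whose 7 days contain one of the six listed holidays.

    Statutory dates are used (no observed-Friday/Monday shifting): a week is
    flagged by the day the holiday falls on, which is what matters for a
    week-level indicator.
    """
    if last_year < first_year:
        raise ValueError("last_year before first_year")
    flagged: set = set()
    holidays: dict[date, str] = {}
    for year in range(first_year, last_year + 1):
        for name, d in holiday_dates(year).items():
            holidays[d] = name
            flagged.add(assign_week(d))
    return HolidayCalendar(flagged, holidays)


# ---------------------------------------------------------------------------
# income quartiles

INCOME_QUARTILES = ["Q1", "Q2", "Q3", "Q4"]


@dataclass
class IncomeLookup:
    """Zip-level median household income over the catchment area.

    Quartiles are computed over the catchment *zip list* (zip-level,
    unweighted), with ties assigned to the lower quartile so the assignment
    is deterministic.
    """

    table: pd.DataFrame  # columns: zip, median_household_income, income_quartile

    @classmethod
    def from_incomes(cls, incomes: pd.DataFrame) -> "IncomeLookup":
        if incomes.empty:
            raise ValueError("empty income lookup")
        tab = incomes[["zip", "median_household_income"]].copy()
        tab["zip"] = tab["zip"].astype(str)
        n = len(tab)
        rank = tab["median_household_income"].rank(method="min")
        q_idx = (np.floor(4.0 * (rank - 1) / n).astype(int) + 1).clip(1, 4)
        tab["income_quartile"] = [INCOME_QUARTILES[i - 1] for i in q_idx]
        return cls(tab)

    @classmethod
    def from_csv(cls, path) -> "IncomeLookup":
        df = pd.read_csv(path, dtype={"zip": str})
        missing = [c for c in ("zip", "median_household_income") if c not in df.columns]
        if missing:
            raise SchemaError(f"income file missing required column(s): {missing}")
        return cls.from_incomes(df)

    def quartile_of(self, zips: pd.Series) -> pd.Series:
        mapping = self.table.set_index("zip")["income_quartile"]
        return zips.astype(str).map(mapping).fillna(MISSING)


def assign_income_quartile(df: pd.DataFrame, lookup: IncomeLookup) -> pd.DataFrame:
    """Label each encounter Q1-Q4 by residence zip, or Missing if unmapped."""
    out = df.copy()
    out["income_quartile"] = lookup.quartile_of(out["zip"])
    return out
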