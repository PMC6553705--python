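"""Wear-time filtering and the twelve weekly behavioral features.

A device day is *valid* when the participant wore the device for at least the
configured threshold (default 1140 minutes = 19 of 24 hours); a worn minute is
one with a recorded heart rate.  Invalid days are removed entirely; a week
keeps whatever valid days remain.

Per participant-week the twelve features are:

* heart rate — mean and **variance** of all worn-minute readings of the
  week's valid days, pooled (population variance: the minute pool is close to
  a census of the week);
* daily steps — mean and **standard deviation** (sample, n-1) of valid-day
  totals;
* four activity states — mean and standard deviation (sample, n-1) of the
  valid-day minutes spent sedentary / lightly / fairly / very active.

The mix of variance for heart rate and standard deviation elsewhere is
deliberate and kept as such throughout; with a single valid day the sample
standard deviations are 0 by convention so no weekly value is undefined
downstream.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ACTIVITY_STATES, MinuteRecord, StudyConfig, assign_week

logger = logging.getLogger("netwell")

#: The 6 weekly-mean behavior features used in the correlation analysis.
BEHAVIOR_MEANS = ("hr_mean", "steps_mean", "sed_mean", "light_mean", "fair_mean", "very_mean")

#: All 12 behavioral features, in fixed column order.
BEHAVIOR_FEATURES = (
    "hr_mean", "hr_var",
    "steps_mean", "steps_sd",
    "sed_mean", "sed_sd",
    "light_mean", "light_sd",
    "fair_mean", "fair_sd",
    "very_mean", "very_sd",
)

_STATE_PREFIX = {"sedentary": "sed", "lightly": "light", "fairly": "fair", "very": "very"}


@dataclasses.dataclass
class DayAggregate:
    participant: str
    date: dt.date
    worn_minutes: int
    daily_steps: int
    state_minutes: dict
    hr_sum: float
    hr_count: int
    valid: bool
    hr_sumsq: float = 0.0


@dataclasses.dataclass
class WeeklyBehavior:
    participant: str
    week: int
    n_valid_days: int
    hr_mean: float = np.nan
    hr_var: float = np.nan
    steps_mean: float = np.nan
    steps_sd: float = np.nan
    sed_mean: float = np.nan
    sed_sd: float = np.nan
    light_mean: float = np.nan
    light_sd: float = np.nan
    fair_mean: float = np.nan
    fair_sd: float = np.nan
    very_mean: float = np.nan
    very_sd: float = np.nan


def daily_aggregate(
    minutes: Sequence[MinuteRecord], config: StudyConfig
) -> DayAggregate:
    """Collapse one participant-day of minute records.

    Worn minutes are those with a non-missing heart rate; the validity flag
    applies the wear-time threshold.
    """
    if not minutes:
        raise ValueError("daily_aggregate requires at least one record")
    participant = minutes[0].participant
    day = minutes[0].timestamp.date()
    if any(r.participant != participant or r.timestamp.date() != day for r in minutes):
        raise ValueError("records must share one participant and one calendar day")

    worn = [r for r in minutes if r.heart_rate is not None]
    state_minutes = {s: 0 for s in ACTIVITY_STATES}
    for r in worn:
        if r.state is not None:
            state_minutes[r.state] += 1
    hr = np.array([r.heart_rate for r in worn], dtype=float)
    return DayAggregate(
        participant=participant,
        date=day,
        worn_minutes=len(worn),
        daily_steps=int(sum(r.steps for r in minutes)),
        state_minutes=state_minutes,
        hr_sum=float(hr.sum()) if worn else 0.0,
        hr_sumsq=float((hr * hr).sum()) if worn else 0.0,
        hr_count=len(worn),
        valid=len(worn) >= config.wear_threshold_min,
    )


def _sd(values: np.ndarray) -> float:
    """Sample (n-1) standard deviation; 0 for a single observation."""
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def weekly_behavior(
    days: Sequence[DayAggregate], participant: str, week: int
) -> WeeklyBehavior:
    """Weekly features from one participant-week of day aggregates; invalid
    days are excluded entirely and a zero-valid-day week yields missing
    features (never an exception)."""
    valid = [d for d in days if d.valid]
    out = WeeklyBehavior(participant=participant, week=week, n_valid_days=len(valid))
    if not valid:
        return out
    hr_count = sum(d.hr_count for d in valid)
    hr_sum = sum(d.hr_sum for d in valid)
    hr_sumsq = sum(d.hr_sumsq for d in valid)
    out.hr_mean = hr_sum / hr_count
    out.hr_var = max(hr_sumsq / hr_count - out.hr_mean**2, 0.0)
    steps = np.array([d.daily_steps for d in valid], dtype=float)
    out.steps_mean = float(steps.mean())
    out.steps_sd = _sd(steps)
    for state, prefix in _STATE_PREFIX.items():
        m = np.array([d.state_minutes[state] for d in valid], dtype=float)
        setattr(out, f"{prefix}_mean", float(m.mean()))
        setattr(out, f"{prefix}_sd", _sd(m))
    return out


# ---------------------------------------------------------------------------
# vectorised table pipeline
# ---------------------------------------------------------------------------

def daily_table_from_minutes(minutes: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Vectorised day aggregation of a minute-level frame (columns
    participant, timestamp, heart_rate, steps, state)."""
    df = minutes.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    worn = df["heart_rate"].notna()
    df["hr"] = df["heart_rate"].astype(float)
    grouped = df.groupby(["participant", "date"], sort=True)
    out = grouped.agg(
        daily_steps=("steps", "sum"),
        hr_sum=("hr", lambda s: s.dropna().sum()),
        hr_sumsq=("hr", lambda s: (s.dropna() ** 2).sum()),
    )
    out["worn_minutes"] = worn.groupby([df["participant"], df["date"]]).sum()
    states = (
        df[worn]
        .pivot_table(index=["participant", "date"], columns="state",
                     values="hr", aggfunc="count")
        .reindex(columns=list(ACTIVITY_STATES), fill_value=0)
    )
    states.columns = ["sedentary", "lightly", "fairly", "very"]
    out = out.join(states).fillna({c: 0 for c in states.columns}).reset_index()
    for c in ("sedentary", "lightly", "fairly", "very", "worn_minutes", "daily_steps"):
        out[c] = out[c].astype(int)
    out["hr_count"] = out["worn_minutes"]
    out["week"] = [assign_week(d, config) for d in out["date"]]
    return out


def weekly_behavior_table(
    daily: pd.DataFrame, config: StudyConfig, min_valid_days: int = 1
) -> pd.DataFrame:
    """Weekly behavioral feature table from a participant-day table.

    Expects the columns produced by :func:`daily_table_from_minutes` or
    :func:`netwell.synthetic_cohort.generate_daily_table`.  Days below the
    wear threshold are dropped (logged); weeks past the study window are
    ignored; participant-weeks with fewer than ``min_valid_days`` valid days
    are dropped from the table.
    """
    df = daily.copy()
    if "week" not in df.columns:
        df["week"] = [assign_week(d, config) for d in df["date"]]
    df = df[df["week"] < config.n_weeks]
    n_before = len(df)
    df = df[df["worn_minutes"] >= config.wear_threshold_min]
    logger.info("wear filter: kept %d of %d participant-days", len(df), n_before)

    def agg(group: pd.DataFrame) -> pd.Series:
        hr_count = group["hr_count"].sum()
        hr_mean = group["hr_sum"].sum() / hr_count
        hr_var = max(group["hr_sumsq"].sum() / hr_count - hr_mean**2, 0.0)
        row = {"hr_mean": hr_mean, "hr_var": hr_var, "n_valid_days": len(group)}
        for col, prefix in [("daily_steps", "steps"), ("sedentary", "sed"),
                            ("lightly", "light"), ("fairly", "fair"), ("very", "very")]:
            vals = group[col].to_numpy(dtype=float)
            row[f"{prefix}_mean"] = vals.mean()
            row[f"{prefix}_sd"] = _sd(vals)
        return pd.Series(row)

    weekly = (
        df.groupby(["participant", "week"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    weekly["n_valid_days"] = weekly["n_valid_days"].astype(int)
    if min_valid_days > 1:
        weekly = weekly[weekly["n_valid_days"] >= min_valid_days]
    return weekly[["participant", "week", *BEHAVIOR_FEATURES, "n_valid_days"]].reset_index(
        drop=True
    )
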