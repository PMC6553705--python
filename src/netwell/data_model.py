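"""Canonical record types, CSV readers/writers and the week-indexing convention.

Every downstream stage consumes the three tables defined here: a communication
event log (calls and texts between opaque string ids), a minute-level wearable
stream (heart rate, steps, activity state) and a per-participant wellness
survey with ordinal Likert labels.  Weeks are consecutive 7-day bins anchored
at the configured study start date — not calendar ISO weeks — so that week
indices are reproducible regardless of locale.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("netwell")

MINUTES_PER_DAY = 1440

#: Valid (inclusive) ranges of the ordinal wellness labels.
ORDINAL_RANGES: dict[str, tuple[int, int]] = {
    "stress": (1, 4),
    "happiness": (1, 4),
    "positive_attitude": (1, 5),
    "health": (1, 4),
}

WELLNESS_ATTRIBUTES = tuple(ORDINAL_RANGES)

ACTIVITY_STATES = ("sedentary", "lightly", "fairly", "very")

GENDERS = ("male", "female", "unreported")


class Channel(str, Enum):
    call = "call"
    text = "text"


class ParseError(ValueError):
    """Raised when an input CSV row cannot be parsed; names the 1-based line."""


class ValidationError(ValueError):
    """Raised when a parsed value violates a domain invariant."""


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Study window, roster and the thresholds shared by all stages.

    Parameters
    ----------
    study_start
        First day of week 0; weeks are 7-day bins from this date.
    n_weeks
        Number of analysed weekly time points (22 mimics a fall semester).
    roster
        Ids of enrolled participants; any other id is an external contact.
    wear_threshold_min
        Minimum worn minutes for a valid device day (1140 = 19 of 24 hours).
    edge_min_events
        Minimum total events over the whole window for a communication edge
        to be kept (the spurious-edge / spam filter).
    """

    study_start: dt.date
    n_weeks: int = 22
    roster: frozenset = frozenset()
    seed: int = 0
    wear_threshold_min: int = 1140
    edge_min_events: int = 3

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValidationError("n_weeks must be >= 1")
        if not 0 <= self.wear_threshold_min <= MINUTES_PER_DAY:
            raise ValidationError("wear_threshold_min must be in [0, 1440]")
        object.__setattr__(self, "roster", frozenset(self.roster))

    @property
    def study_end(self) -> dt.date:
        """Exclusive end date of the analysis window."""
        return self.study_start + dt.timedelta(days=7 * self.n_weeks)


@dataclasses.dataclass(frozen=True)
class CommEvent:
    timestamp: dt.datetime
    source: str
    target: str
    channel: Channel
    duration_s: float | None = None
    answered: bool | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError("self-loop event (source == target)")
        if self.duration_s is not None and self.duration_s < 0:
            raise ValidationError("duration_s must be nonnegative")


@dataclasses.dataclass(frozen=True)
class MinuteRecord:
    participant: str
    timestamp: dt.datetime
    heart_rate: float | None = None
    steps: int = 0
    state: str | None = None

    def __post_init__(self) -> None:
        if self.heart_rate is not None and self.heart_rate <= 0:
            raise ValidationError("heart_rate must be positive when present")
        if self.steps < 0:
            raise ValidationError("steps must be nonnegative")
        if self.state is not None and self.state not in ACTIVITY_STATES:
            raise ValidationError(f"unknown activity state {self.state!r}")


@dataclasses.dataclass(frozen=True)
class SurveyRecord:
    participant: str
    gender: str = "unreported"
    stress: int | None = None
    happiness: int | None = None
    positive_attitude: int | None = None
    health: int | None = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        for attr, (lo, hi) in ORDINAL_RANGES.items():
            value = getattr(self, attr)
            if value is not None and not lo <= value <= hi:
                raise ValidationError(
                    f"{attr}={value} outside ordinal range [{lo}, {hi}]"
                )


def assign_week(timestamp: dt.datetime | dt.date, config: StudyConfig) -> int:
    """Map a timestamp to its 0-based week index: floor(days since start / 7).

    Raises for timestamps before the study start.  Indices >= ``n_weeks`` are
    returned as-is; callers treat them as out-of-window (see
    :func:`in_window`).
    """
    day = timestamp.date() if isinstance(timestamp, dt.datetime) else timestamp
    days = (day - config.study_start).days
    if days < 0:
        raise ValidationError(f"timestamp {timestamp} precedes study start")
    return days // 7


def in_window(timestamp: dt.datetime | dt.date, config: StudyConfig) -> bool:
    day = timestamp.date() if isinstance(timestamp, dt.datetime) else timestamp
    if day < config.study_start:
        return False
    return assign_week(day, config) < config.n_weeks


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("timestamp", "source", "target", "channel")
_MINUTE_COLUMNS = ("participant", "timestamp", "heart_rate", "steps", "state")
_SURVEY_COLUMNS = ("participant", "gender") + WELLNESS_ATTRIBUTES


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing} in header")


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed timestamp {raw[bad.idxmax()]!r} at line {line}")
    if parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise ParseError(f"{path}: empty timestamp at line {line}")
    return parsed


def read_events(path, config: StudyConfig) -> list[CommEvent]:
    """Read a communication log CSV, dropping out-of-window rows and self-loops.

    Both drops are counted and logged; a malformed timestamp or a missing
    required column raises :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    _require_columns(df, _EVENT_COLUMNS, path)
    if df.empty:
        return []
    ts = _parse_timestamps(df["timestamp"], path)

    events: list[CommEvent] = []
    n_out, n_self = 0, 0
    has_dur = "duration_s" in df.columns
    has_ans = "answered" in df.columns
    for i, row in df.iterrows():
        t = ts[i].to_pydatetime()
        if not in_window(t, config):
            n_out += 1
            continue
        if row["source"] == row["target"]:
            n_self += 1
            continue
        channel = str(row["channel"]).strip()
        if channel not in (Channel.call.value, Channel.text.value):
            raise ParseError(f"{path}: unknown channel {channel!r} at line {i + 2}")
        dur = None
        if has_dur and pd.notna(row["duration_s"]):
            dur = float(row["duration_s"])
        ans = None
        if has_ans and pd.notna(row["answered"]):
            ans = str(row["answered"]).strip().lower() in ("true", "1", "yes")
        events.append(
            CommEvent(t, str(row["source"]), str(row["target"]), Channel(channel), dur, ans)
        )
    if n_out:
        logger.info("read_events: dropped %d out-of-window row(s) from %s", n_out, path)
    if n_self:
        logger.warning("read_events: rejected %d self-loop row(s) from %s", n_self, path)
    return events


def write_events(events: Iterable[CommEvent], path) -> None:
    rows = [
        {
            "timestamp": e.timestamp.isoformat(),
            "source": e.source,
            "target": e.target,
            "channel": e.channel.value,
            "duration_s": e.duration_s,
            "answered": e.answered,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(_EVENT_COLUMNS) + ["duration_s", "answered"]).to_csv(
        path, index=False
    )


def read_minutes(path, config: StudyConfig) -> list[MinuteRecord]:
    """Read the minute-level wearable stream.

    A missing heart rate marks a non-worn minute.  Duplicate participant-minute
    rows are resolved keep-first with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant": str})
    _require_columns(df, _MINUTE_COLUMNS, path)
    if df.empty:
        return []
    ts = _parse_timestamps(df["timestamp"], path)

    records: list[MinuteRecord] = []
    seen: set[tuple[str, dt.datetime]] = set()
    n_dup = 0
    for i, row in df.iterrows():
        t = ts[i].to_pydatetime().replace(second=0, microsecond=0)
        key = (str(row["participant"]), t)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        hr = float(row["heart_rate"]) if pd.notna(row["heart_rate"]) else None
        state = str(row["state"]) if pd.notna(row["state"]) else None
        try:
            records.append(
                MinuteRecord(str(row["participant"]), t, hr, int(row["steps"] or 0), state)
            )
        except ValidationError as err:
            raise ParseError(f"{path}: line {i + 2}: {err}") from err
    if n_dup:
        logger.warning("read_minutes: kept first of %d duplicate minute(s) in %s", n_dup, path)
    return records


def write_minutes(records: Iterable[MinuteRecord], path) -> None:
    rows = [
        {
            "participant": r.participant,
            "timestamp": r.timestamp.isoformat(),
            "heart_rate": r.heart_rate,
            "steps": r.steps,
            "state": r.state,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_MINUTE_COLUMNS)).to_csv(path, index=False)


def read_survey(path) -> list[SurveyRecord]:
    """Read the survey table, validating each ordinal against its Likert range."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant": str})
    _require_columns(df, _SURVEY_COLUMNS, path)
    records: list[SurveyRecord] = []
    for i, row in df.iterrows():
        kwargs: dict = {"participant": str(row["participant"])}
        gender = row["gender"]
        kwargs["gender"] = str(gender) if pd.notna(gender) else "unreported"
        for attr in WELLNESS_ATTRIBUTES:
            kwargs[attr] = int(row[attr]) if pd.notna(row[attr]) else None
        try:
            records.append(SurveyRecord(**kwargs))
        except ValidationError as err:
            raise ParseError(f"{path}: line {i + 2}: {err}") from err
    return records


def write_survey(records: Iterable[SurveyRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(_SURVEY_COLUMNS))
    for attr in WELLNESS_ATTRIBUTES:
        df[attr] = df[attr].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DataFrame views (the vectorised stages work on frames, not record lists)
# ---------------------------------------------------------------------------

def events_frame(events: Sequence[CommEvent], config: StudyConfig) -> pd.DataFrame:
    """Tabular view of an event list with the week index pre-assigned."""
    if not events:
        return pd.DataFrame(columns=["timestamp", "source", "target", "channel", "week"])
    df = pd.DataFrame(
        {
            "timestamp": [e.timestamp for e in events],
            "source": [e.source for e in events],
            "target": [e.target for e in events],
            "channel": [e.channel.value for e in events],
        }
    )
    start = pd.Timestamp(config.study_start)
    df["week"] = ((df["timestamp"] - start).dt.days // 7).astype(int)
    return df


def minutes_frame(records: Sequence[MinuteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant for r in records],
            "timestamp": [r.timestamp for r in records],
            "heart_rate": [r.heart_rate for r in records],
            "steps": [r.steps for r in records],
            "state": [r.state for r in records],
        }
    )


def survey_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
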