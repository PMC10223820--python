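"""Time-stamped diet-diary ingestion and eating-window computation.

Diaries follow the smartphone-app convention of one row per logged item:
participant, calendar date, clock time, one of five categories (breakfast,
lunch, dinner, snack, drink), free-text item, and a caloric flag. Only
caloric events define the eating window; plain water, black tea/coffee and
other energy-free drinks are permitted during the fasting phase and are
logged as non-caloric drinks.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .timeutils import parse_clock, to_eating_day

__all__ = [
    "Category",
    "DiaryEvent",
    "EatingWindow",
    "read_diary",
    "caloric_events",
    "daily_window",
    "daily_windows",
    "mean_times",
]


class Category(str, enum.Enum):
    BREAKFAST = "breakfast"
    LUNCH = "lunch"
    DINNER = "dinner"
    SNACK = "snack"
    DRINK = "drink"


@dataclass(frozen=True)
class DiaryEvent:
    """One logged intake occasion, keyed to its eating day.

    ``time`` is minutes since midnight of ``eating_day``; post-midnight
    entries (logged before 04:00) carry the previous date as eating_day and
    a time >= 1440.
    """

    participant: str
    eating_day: dt.date
    time: float
    category: Category
    item: str
    caloric: bool


@dataclass(frozen=True)
class EatingWindow:
    """First/last caloric intake of one eating day, in eating-day minutes."""

    eating_day: dt.date
    first_intake: float
    last_intake: float

    @property
    def duration(self) -> float:
        """Window length in hours."""
        return (self.last_intake - self.first_intake) / 60.0


_DIARY_COLUMNS = ["participant", "date", "time", "category", "item", "caloric"]
_TRUTHY = {"true", "1", "yes", "y"}
_FALSY = {"false", "0", "no", "n"}


def _parse_caloric(raw: str, lineno: int) -> bool:
    val = str(raw).strip().lower()
    if val in _TRUTHY:
        return True
    if val in _FALSY:
        return False
    raise ValueError(f"line {lineno}: caloric flag {raw!r} is not boolean")


def read_diary(path: str | Path) -> list[DiaryEvent]:
    """Read a delimited diary file into events sorted by participant, time.

    Expects a header ``participant,date,time,category,item,caloric``.
    Entries timed before 04:00 are assigned to the previous eating day with
    their clock time shifted past 24:00. Malformed rows raise with their
    line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"diary file {path} contains no records")
    missing = set(_DIARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"diary file {path} lacks columns {sorted(missing)}")

    events = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            category = Category(row["category"].strip().lower())
        except ValueError:
            raise ValueError(
                f"line {lineno}: unknown diary category {row['category']!r}"
            ) from None
        try:
            date = dt.date.fromisoformat(row["date"].strip())
            minutes = parse_clock(row["time"])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        eating_day, minutes = to_eating_day(date, minutes)
        events.append(DiaryEvent(
            participant=row["participant"].strip(),
            eating_day=eating_day,
            time=minutes,
            category=category,
            item=row["item"],
            caloric=_parse_caloric(row["caloric"], lineno),
        ))
    events.sort(key=lambda e: (e.participant, e.eating_day, e.time))
    return events


def caloric_events(events: list[DiaryEvent]) -> list[DiaryEvent]:
    """Keep the events that count as energy intake.

    Food categories always count (the app's caloric flag is advisory for
    food); drinks count only when flagged caloric, so permitted fasting
    drinks (water, black tea/coffee, sugar-free drinks) drop out while a
    latte stays in.
    """
    return [e for e in events if e.category is not Category.DRINK or e.caloric]


def daily_window(events: list[DiaryEvent]) -> EatingWindow | None:
    """Eating window of one eating day from its events.

    Returns None when the day has no caloric events ("no diary data",
    distinct from a zero-length window from a single occasion).
    """
    kept = caloric_events(events)
    if not kept:
        return None
    days = {e.eating_day for e in kept}
    if len(days) != 1:
        raise ValueError(f"events span multiple eating days: {sorted(days)}")
    times = [e.time for e in kept]
    return EatingWindow(eating_day=kept[0].eating_day,
                        first_intake=min(times), last_intake=max(times))


def daily_windows(events: list[DiaryEvent]) -> dict[dt.date, EatingWindow]:
    """Per-eating-day windows for one participant's events."""
    by_day: dict[dt.date, list[DiaryEvent]] = {}
    for e in events:
        by_day.setdefault(e.eating_day, []).append(e)
    out = {}
    for day in sorted(by_day):
        window = daily_window(by_day[day])
        if window is not None:
            out[day] = window
    return out


def mean_times(windows: list[EatingWindow]) -> tuple[float, float, float, int]:
    """Arithmetic means of first times, last times and durations.

    Returns ``(mean_first, mean_last, mean_duration_hours, n_days)``. Times
    stay on the minutes-since-midnight scale (post-midnight values > 1440
    enter as-is); the eating-day convention keeps each endpoint on one
    contiguous span, so plain (non-circular) means are valid.
    """
    if not windows:
        raise ValueError("mean_times needs at least one eating window")
    n = len(windows)
    mean_first = sum(w.first_intake for w in windows) / n
    mean_last = sum(w.last_intake for w in windows) / n
    mean_duration = sum(w.duration for w in windows) / n
    return mean_first, mean_last, mean_duration, n
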