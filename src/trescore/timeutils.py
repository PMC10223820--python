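"""Clock-time helpers built around the wake-to-wake "eating day".

All clock times in this package are minutes since midnight of the eating
day to which they belong. An eating day runs 04:00–04:00 local, so intake
logged after midnight but before 04:00 belongs to the *previous* calendar
date and is represented with a value >= 1440 (e.g. 01:30 -> 25:30 -> 1530).
This keeps every eating window a single contiguous span, which is what
makes plain arithmetic means of clock times valid.
"""

from __future__ import annotations

import datetime as dt

#: Minutes after midnight at which a new eating day starts (04:00).
EATING_DAY_START = 240

#: Minutes in a day.
DAY_MINUTES = 1440


def parse_clock(text: str) -> float:
    """Parse ``HH:MM`` into minutes since midnight.

    Hours >= 24 are accepted (post-midnight times already expressed in the
    eating-day convention, e.g. ``25:30``).
    """
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"not a HH:MM clock time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if h < 0 or not (0 <= m < 60):
        raise ValueError(f"not a HH:MM clock time: {text!r}")
    return float(h * 60 + m)


def format_clock(minutes: float) -> str:
    """Render minutes since midnight as ``HH:MM`` (hours may exceed 23)."""
    total = int(round(minutes))
    return f"{total // 60:02d}:{total % 60:02d}"


def to_eating_day(date: dt.date, minutes: float) -> tuple[dt.date, float]:
    """Map a calendar (date, minutes-past-midnight) onto its eating day.

    Times before 04:00 belong to the previous date's eating day and come
    back shifted by 24 h.
    """
    if minutes < EATING_DAY_START:
        return date - dt.timedelta(days=1), minutes + DAY_MINUTES
    return date, minutes


def eating_day_of_timestamp(ts: dt.datetime) -> dt.date:
    """Eating day owning an absolute timestamp (04:00–04:00 span)."""
    day, _ = to_eating_day(ts.date(), ts.hour * 60 + ts.minute + ts.second / 60)
    return day


def eating_day_span(day: dt.date) -> tuple[dt.datetime, dt.datetime]:
    """Absolute [start, end) span of an eating day: 04:00 to next 04:00."""
    start = dt.datetime.combine(day, dt.time(4, 0))
    return start, start + dt.timedelta(days=1)


def minutes_within_day(ts: dt.datetime, day: dt.date) -> float:
    """Clock time of ``ts`` expressed on ``day``'s eating-day scale."""
    return (ts - dt.datetime.combine(day, dt.time(0, 0))).total_seconds() / 60.0
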