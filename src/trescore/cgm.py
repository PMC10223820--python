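"""CGM trace ingestion and sustained glucose-excursion detection.

Flash-monitor exports (nominal 15-min cadence, mmol/L) are scanned for
sustained elevations that mark eating occasions: glucose at least
1 mmol/L above a local pre-rise reference, continuously, for at least an
hour. The reference for each candidate onset is the minimum glucose over
the preceding 30 min, which tracks slow circadian drift without absorbing
the meal rise itself. Detected excursions are the objective evidence used
to cross-check self-reported eating times.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .study_model import ProtocolTargets
from .timeutils import eating_day_span

__all__ = [
    "CGMTrace",
    "GlucoseExcursion",
    "DailyGlucoseEvents",
    "read_cgm",
    "detect_excursions",
    "daily_glucose_events",
    "exclude_sleep_onsets",
]

#: A hole longer than this (minutes) breaks the continuity of an elevation:
#: we cannot certify ">= 1 h elevated" across it. Two nominal cadences.
MAX_SUSTAIN_GAP = 30.0


@dataclass
class CGMTrace:
    """One participant's glucose series.

    ``times`` is a strictly increasing DatetimeIndex; ``glucose`` the
    matching readings in mmol/L. Gaps are derivable (interval > 2x cadence),
    not stored.
    """

    participant: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    nominal_cadence: float = 15.0

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose lengths differ")
        if len(self.times) > 1 and not (np.diff(self.times.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(self.glucose) and not (self.glucose > 0).all():
            raise ValueError("glucose readings must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def minutes(self) -> np.ndarray:
        """Sample times as float minutes since the first sample."""
        if len(self.times) == 0:
            return np.empty(0)
        return (self.times.asi8 - self.times.asi8[0]) / 60e9

    def gaps(self) -> list[tuple[dt.datetime, dt.datetime]]:
        """Flanking timestamps of every hole longer than twice the cadence."""
        out = []
        deltas = np.diff(self.times.asi8) / 60e9
        for i in np.nonzero(deltas > 2 * self.nominal_cadence)[0]:
            out.append((self.times[i].to_pydatetime(),
                        self.times[i + 1].to_pydatetime()))
        return out


@dataclass(frozen=True)
class GlucoseExcursion:
    """A sustained elevation: onset/end timestamps, pre-rise reference and
    peak glucose (mmol/L), and how long the elevation was sustained."""

    onset: dt.datetime
    end: dt.datetime
    reference: float
    peak: float
    sustained_minutes: float


@dataclass(frozen=True)
class DailyGlucoseEvents:
    """Excursion summary of one eating day (04:00-04:00 span)."""

    eating_day: dt.date
    first_onset: dt.datetime | None
    last_onset: dt.datetime | None
    n_excursions: int
    coverage_fraction: float
    missing: bool


def read_cgm(path: str | Path) -> CGMTrace:
    """Read a single-participant CGM export.

    Expects header ``participant,timestamp,glucose_mmol_l`` with ISO-8601
    timestamps. Duplicate timestamps collapse to their mean reading;
    non-positive glucose rows are rejected with their line numbers.
    """
    df = pd.read_csv(path, dtype={"participant": str})
    if df.empty:
        raise ValueError(f"CGM file {path} contains no records")
    missing = {"participant", "timestamp", "glucose_mmol_l"} - set(df.columns)
    if missing:
        raise ValueError(f"CGM file {path} lacks columns {sorted(missing)}")
    participants = df["participant"].unique()
    if len(participants) != 1:
        raise ValueError(
            f"CGM file {path} mixes participants {sorted(participants)}; "
            "one trace per file")
    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = df.index[~(glucose > 0)] + 2  # header is line 1
    if len(bad):
        raise ValueError(
            f"CGM file {path}: non-positive or unreadable glucose at "
            f"lines {list(bad)}")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"CGM file {path}: unparseable timestamp ({exc})") from None
    collapsed = (pd.DataFrame({"t": stamps, "g": glucose})
                 .groupby("t", sort=True)["g"].mean())
    return CGMTrace(participant=str(participants[0]),
                    times=pd.DatetimeIndex(collapsed.index),
                    glucose=collapsed.to_numpy())


def detect_excursions(trace: CGMTrace,
                      params: ProtocolTargets) -> list[GlucoseExcursion]:
    """Find sustained eating-driven elevations in a trace.

    For each candidate onset sample the pre-rise reference is the minimum
    glucose over the preceding 30 min (the window is clipped at the trace
    start; a candidate with no reference sample in that window — the first
    sample, or a sample right after a long hole — cannot be certified and
    is skipped). An excursion is emitted when glucose stays at or above
    reference + ``params.glucose_threshold`` with no sample below and no
    gap longer than 30 min, for at least ``params.min_elevation_duration``.
    Overlapping or abutting qualifying stretches merge into one excursion.
    Results are sorted by onset.
    """
    n = len(trace)
    if n == 0:
        return []
    t = trace.minutes()
    g = trace.glucose
    thr = params.glucose_threshold
    min_dur = params.min_elevation_duration

    # qualifying stretches as (i, j, reference) with maximal j per onset i
    stretches: list[tuple[int, int, float]] = []
    for i in range(1, n):
        in_ref = (t >= t[i] - 30.0) & (t < t[i])
        if not in_ref.any():
            continue
        ref = g[in_ref].min()
        if g[i] < ref + thr:
            continue
        j = i
        while (j + 1 < n and t[j + 1] - t[j] <= MAX_SUSTAIN_GAP
               and g[j + 1] >= ref + thr):
            j += 1
        if t[j] - t[i] >= min_dur:
            stretches.append((i, j, ref))

    # merge overlapping/abutting stretches (gap smaller than one cadence)
    merged: list[list] = []
    for i, j, ref in stretches:
        if merged and t[i] - t[merged[-1][1]] <= trace.nominal_cadence:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j, ref])

    out = []
    for i, j, ref in merged:
        out.append(GlucoseExcursion(
            onset=trace.times[i].to_pydatetime(),
            end=trace.times[j].to_pydatetime(),
            reference=float(ref),
            peak=float(g[i:j + 1].max()),
            sustained_minutes=float(t[j] - t[i]),
        ))
    return out


def daily_glucose_events(excursions: list[GlucoseExcursion],
                         trace: CGMTrace,
                         eating_day: dt.date,
                         missing_coverage: float = 0.5) -> DailyGlucoseEvents:
    """Summarize the excursions of one eating day.

    Coverage is the fraction of samples present over the 04:00-04:00 span
    at the trace's nominal cadence; a day below ``missing_coverage``
    (default 0.5) is flagged missing and should not be scored.
    """
    start, end = eating_day_span(eating_day)
    onsets = sorted(e.onset for e in excursions if start <= e.onset < end)
    expected = 1440.0 / trace.nominal_cadence
    present = int(((trace.times >= start) & (trace.times < end)).sum())
    coverage = min(present / expected, 1.0)
    return DailyGlucoseEvents(
        eating_day=eating_day,
        first_onset=onsets[0] if onsets else None,
        last_onset=onsets[-1] if onsets else None,
        n_excursions=len(onsets),
        coverage_fraction=coverage,
        missing=coverage < missing_coverage,
    )


def exclude_sleep_onsets(excursions: list[GlucoseExcursion],
                         sleep_start: float,
                         sleep_end: float) -> list[GlucoseExcursion]:
    """Drop excursions whose onset falls inside a declared sleep interval.

    The interval is given in minutes since midnight and may wrap midnight
    (e.g. 23:00-07:00 as 1380, 420). Waking (dawn) excursions are kept by
    default in the pipeline; this filter backs the opt-in switch for
    suppressing them.
    """
    def asleep(ts: dt.datetime) -> bool:
        m = ts.hour * 60 + ts.minute + ts.second / 60
        if sleep_start <= sleep_end:
            return sleep_start <= m < sleep_end
        return m >= sleep_start or m < sleep_end

    return [e for e in excursions if not asleep(e.onset)]
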