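"""Per-day adherence scoring and phase-level aggregation.

A TRE day is adherent when all applicable criteria hold:

(i)   the eating window is reduced by 3 h from the baseline mean (within
      the 30-min allowance) AND is no longer than 12 h;
(ii)  first and last reported intakes sit within 30 min of the shifted
      targets (baseline first + 1.5 h, baseline last - 1.5 h);
(iii) detected glucose onsets fall within 30 min of the reported first and
      last intake times (the objective CGM cross-check).

Control days are non-adherent when the reported window shrinks below 12 h
(controls must keep habitual eating). Days without CGM coverage score as
missing and drop out of the denominator; the adherence rate is
100 x adherent / available days, the days-per-week rate 7 x that fraction.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np

from .cgm import DailyGlucoseEvents
from .diet_diary import EatingWindow
from .study_model import Group, ProtocolTargets, StudyPhase
from .timeutils import minutes_within_day

__all__ = [
    "DayAdherenceRecord",
    "PhaseSummary",
    "score_tre_day",
    "score_control_day",
    "adherence_percent",
    "phase_summary",
    "group_phase_summary",
    "combine_phases",
    "round_half_up",
]


@dataclass(frozen=True)
class DayAdherenceRecord:
    """Criterion outcomes of one 24 h period.

    Criterion fields are True/False when evaluable and None (n/a) when
    their inputs are unavailable; ``adherent`` is the conjunction of the
    applicable criteria, or None (missing) when the day cannot be scored.
    """

    eating_day: dt.date
    group: Group
    criterion_window_reduced: bool | None = None
    criterion_window_le_12h: bool | None = None
    criterion_times_shifted: bool | None = None
    criterion_glucose_match: bool | None = None
    adherent: bool | None = None
    cgm_available: bool = True
    diary_available: bool = True


@dataclass(frozen=True)
class PhaseSummary:
    """Adherence of one participant (or group mean) over one phase."""

    phase: str
    adherent_days: int
    available_days: int

    @property
    def percent(self) -> float | None:
        if self.available_days == 0:
            return None
        return 100.0 * self.adherent_days / self.available_days

    @property
    def days_per_week(self) -> float | None:
        if self.available_days == 0:
            return None
        return 7.0 * self.adherent_days / self.available_days


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as trial reports print (2.5 -> 3)."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _within(value: float, target: float, tolerance: float) -> bool:
    return abs(value - target) <= tolerance


def score_tre_day(window: EatingWindow | None,
                  targets: ProtocolTargets,
                  events: DailyGlucoseEvents | None,
                  group: Group = Group.TRE) -> DayAdherenceRecord:
    """Score one intervention day of a TRE participant.

    ``window`` is the day's diary-derived eating window (None when no
    diary data), ``targets`` the participant's baseline-derived protocol
    targets, ``events`` the day's CGM excursion summary (None or flagged
    missing when the sensor was down). Any criterion lacking its inputs is
    recorded n/a; a day without CGM cannot be objectively scored and its
    ``adherent`` is missing.
    """
    if group is not Group.TRE:
        raise ValueError("score_tre_day applies to the TRE arm only")

    cgm_ok = events is not None and not events.missing
    diary_ok = window is not None
    day = window.eating_day if diary_ok else (
        events.eating_day if events is not None else None)

    reduced = le12 = shifted = match = None
    if diary_ok:
        duration_min = window.last_intake - window.first_intake
        reduction = targets.baseline_window - duration_min
        reduced = reduction >= targets.required_reduction - targets.window_tolerance
        le12 = duration_min <= targets.max_window
        shifted = (_within(window.first_intake, targets.target_first,
                           targets.window_tolerance)
                   and _within(window.last_intake, targets.target_last,
                               targets.window_tolerance))
    if diary_ok and cgm_ok:
        if events.first_onset is None or events.last_onset is None:
            match = False
        else:
            tol = targets.glucose_match_tolerance
            first_onset = minutes_within_day(events.first_onset, day)
            last_onset = minutes_within_day(events.last_onset, day)
            match = (_within(first_onset, window.first_intake, tol)
                     and _within(last_onset, window.last_intake, tol))

    criteria = (reduced, le12, shifted, match)
    adherent = None
    if cgm_ok and all(c is not None for c in criteria):
        adherent = all(criteria)

    return DayAdherenceRecord(
        eating_day=day,
        group=group,
        criterion_window_reduced=reduced,
        criterion_window_le_12h=le12,
        criterion_times_shifted=shifted,
        criterion_glucose_match=match,
        adherent=adherent,
        cgm_available=cgm_ok,
        diary_available=diary_ok,
    )


def score_control_day(window: EatingWindow | None,
                      group: Group = Group.CONTROL,
                      min_window_hours: float = 12.0,
                      eating_day: dt.date | None = None) -> DayAdherenceRecord:
    """Score a control day: adherent iff the habitual window stays >= 12 h.

    Also used for TRE baseline (W0) days, where no shifted targets exist
    yet and adherence means maintaining the habitual >= 12 h window. A day
    without diary data scores missing.
    """
    if window is None:
        return DayAdherenceRecord(eating_day=eating_day, group=group,
                                  adherent=None, diary_available=False)
    return DayAdherenceRecord(
        eating_day=window.eating_day,
        group=group,
        adherent=window.duration >= min_window_hours,
    )


def adherence_percent(records: list[DayAdherenceRecord]) -> float | None:
    """Percent of available days adherent, per the trial's formula.

    Numerator: days coded adherent. Denominator: days with a non-missing
    code — when CGM (or diary) data are missing the available-day count is
    recalculated rather than charging the day as non-adherent. Returns
    None (undefined, not 0) when no day is available.
    """
    available = [r for r in records if r.adherent is not None]
    if not available:
        return None
    return 100.0 * sum(r.adherent for r in available) / len(available)


def phase_summary(records: list[DayAdherenceRecord],
                  phase: StudyPhase,
                  day_of: dict[dt.date, int]) -> PhaseSummary:
    """One participant's adherent/available counts over a phase.

    ``day_of`` maps eating days to study-day indices (day 1 = first
    intervention day) so records can be filtered to the phase's range.
    """
    in_phase = [r for r in records
                if r.eating_day is not None
                and day_of.get(r.eating_day) in phase.days()]
    available = [r for r in in_phase if r.adherent is not None]
    return PhaseSummary(phase=phase.label,
                        adherent_days=sum(r.adherent for r in available),
                        available_days=len(available))


def group_phase_summary(percents: list[float]) -> tuple[float, float, int]:
    """Group mean and SEM of per-participant phase percentages."""
    vals = np.asarray([p for p in percents if p is not None], dtype=float)
    if len(vals) == 0:
        raise ValueError("no participant percentages to summarize")
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sem, len(vals)


def combine_phases(w2: float | None, w5: float | None,
                   weights: tuple[float, float] | None = None) -> float | None:
    """Overall intervention adherence from the two phase rates.

    The default is the unweighted arithmetic mean of the W2 and W5 rates,
    which is how the trial's summary combines them; pass
    ``weights=(14, 21)`` for a day-weighted variant. Missing propagates.
    """
    if w2 is None or w5 is None:
        return None
    if weights is None:
        return (w2 + w5) / 2.0
    a, b = weights
    return (a * w2 + b * w5) / (a + b)
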