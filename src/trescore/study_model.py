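"""Shared trial vocabulary: participants, protocol targets, study phases.

The trial design is a 2-week baseline followed by 5 weeks of either
time-restricted eating (TRE) or habitual eating (control). TRE participants
shrink their habitual eating window by 3 h, symmetrically: first intake is
delayed and last intake advanced by 1.5 h each relative to the baseline
mean times, with a +/-30 min allowance. This module holds the domain types,
the eligibility screen, and the derivation of per-participant targets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

__all__ = [
    "Group",
    "Sex",
    "ParticipantProfile",
    "ProtocolTargets",
    "StudyPhase",
    "PHASES",
    "EligibilityResult",
    "check_eligibility",
    "derive_protocol_targets",
]


class Group(str, enum.Enum):
    TRE = "TRE"
    CONTROL = "CONTROL"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


@dataclass(frozen=True)
class ParticipantProfile:
    """Screening characteristics of one participant.

    ``baseline_window`` is the habitual eating window in hours, as declared
    at screening (eligibility requires >= 12 h).
    """

    id: str
    group: Group
    sex: Sex
    age: float
    weight: float
    bmi: float
    systolic_bp: float
    diastolic_bp: float
    baseline_window: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) is None:
                raise ValueError(f"profile field {f.name!r} is missing")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class ProtocolTargets:
    """Per-participant protocol constants, derived from baseline eating times.

    All clock times are minutes since midnight of the eating day; durations
    are minutes unless the name says otherwise. Defaults encode the trial
    protocol (1.5 h shifts, 3 h reduction, <=12 h window, +/-30 min
    allowances, >=1 mmol/L for >=60 min excursions, 35 intervention days)
    and are overridable for sensitivity analysis.
    """

    baseline_first: float
    baseline_last: float
    shift: float = 90.0
    window_tolerance: float = 30.0
    required_reduction: float = 180.0
    max_window: float = 720.0
    glucose_threshold: float = 1.0
    min_elevation_duration: float = 60.0
    glucose_match_tolerance: float = 30.0
    intervention_days: int = 35
    target_first: float = field(init=False)
    target_last: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("shift", "window_tolerance", "required_reduction",
                     "max_window", "min_elevation_duration",
                     "glucose_match_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "target_first", self.baseline_first + self.shift)
        object.__setattr__(self, "target_last", self.baseline_last - self.shift)

    @property
    def baseline_window(self) -> float:
        return self.baseline_last - self.baseline_first

    @property
    def target_window(self) -> float:
        return self.target_last - self.target_first


@dataclass(frozen=True)
class StudyPhase:
    """Assessment phase with inclusive day indices relative to intervention
    start (day 1 = first intervention day; day 0 = last baseline day)."""

    label: str
    day_range: tuple[int, int]

    def days(self) -> range:
        return range(self.day_range[0], self.day_range[1] + 1)

    def __contains__(self, day: int) -> bool:
        return self.day_range[0] <= day <= self.day_range[1]


#: W0 = last week of baseline; W2 = intervention days 1-14; W5 = days 15-35.
PHASES: dict[str, StudyPhase] = {
    "W0": StudyPhase("W0", (-6, 0)),
    "W2": StudyPhase("W2", (1, 14)),
    "W5": StudyPhase("W5", (15, 35)),
}


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    failed_rules: tuple[str, ...]


#: rule name -> predicate on the profile; a participant is eligible iff all hold.
_ELIGIBILITY_RULES = {
    "bmi": lambda p: 18.5 <= p.bmi <= 29.9,
    "age": lambda p: 18 <= p.age <= 50,
    "systolic_bp": lambda p: p.systolic_bp < 140,
    "diastolic_bp": lambda p: p.diastolic_bp < 90,
    "eating_window": lambda p: p.baseline_window >= 12,
}


def check_eligibility(profile: ParticipantProfile) -> EligibilityResult:
    """Screen a participant against the recruitment rules.

    Eligible iff non-obese (BMI 18.5–29.9), aged 18–50, normotensive
    (<140/90 mmHg on both readings, strictly) and with a habitual eating
    window of at least 12 h. Every failed rule is named in the result.
    """
    failed = tuple(name for name, rule in _ELIGIBILITY_RULES.items()
                   if not rule(profile))
    return EligibilityResult(eligible=not failed, failed_rules=failed)


def derive_protocol_targets(
    baseline_first: float,
    baseline_last: float,
    **overrides: float,
) -> ProtocolTargets:
    """Turn baseline mean first/last eating times into intervention targets.

    Target first intake = baseline first + shift (default 1.5 h); target
    last intake = baseline last - shift; so the target window is exactly
    ``required_reduction`` (default 3 h) shorter than baseline.

    Parameters
    ----------
    baseline_first, baseline_last
        Baseline mean eating times, minutes since midnight of the eating
        day (post-midnight last intake is expressed as > 1440).
    **overrides
        Any ``ProtocolTargets`` constant, e.g. ``shift=120``.

    Raises
    ------
    ValueError
        If the baseline window is shorter than the required reduction
        (targets would invert).
    """
    targets = ProtocolTargets(baseline_first=baseline_first,
                              baseline_last=baseline_last, **overrides)
    if targets.baseline_window < targets.required_reduction:
        raise ValueError(
            f"baseline window {targets.baseline_window:.0f} min is shorter than "
            f"the required reduction {targets.required_reduction:.0f} min")
    return targets
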