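"""Synthetic cohort generator with known ground truth.

Emulates the three data streams of a TRE trial — time-stamped diet
diaries, flash-CGM glucose traces, and exit-questionnaire responses — for
a cohort of TRE and control participants, so every pipeline stage can be
exercised and validated without the (undeposited) study data.

Each participant gets habitual baseline eating times (window >= 12 h),
protocol targets derived exactly as the pipeline derives them, and a
Bernoulli per-day behavioural state: an adherent intervention day places
meals inside the target window with first/last intake within the 30-min
allowance; a violated day is, in equal parts, an early first intake, a
late last intake, or an unreported late-evening meal that appears in the
CGM trace but not in the diary (the scenario the objective criterion is
meant to catch). Glucose is basal + a low-amplitude circadian rhythm + a
dawn rise at waking + a gamma-like kernel per meal + Gaussian sensor
noise; whole-day sensor dropouts emit no samples.

All times are drawn on the 15-min grid: self-reported diary times are
quarter-hour rounded in practice, and the sensor samples on the same
nominal cadence.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .study_model import Group, derive_protocol_targets
from .timeutils import DAY_MINUTES, EATING_DAY_START, format_clock

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "simulate_glucose_day",
    "simulate_participant",
    "simulate_cohort",
    "simulate_study",
]

#: Per-group questionnaire responses are drawn around these central values
#: (day-frequency items in days/week, ease on 1-5, restriction in hours),
#: mirroring the scale of responses a small TRE cohort produces.
_QUESTIONNAIRE_CENTERS = {
    Group.TRE: {"ease": 3.1, "morning_days": 4.9, "evening_days": 4.1,
                "window_days": 4.3, "plan_days": 3.0, "realistic_days": 4.6,
                "restrict_hours": 3.6},
    Group.CONTROL: {"ease": 3.3, "morning_days": 3.4, "evening_days": 2.8,
                    "window_days": 3.0, "plan_days": 3.4,
                    "realistic_days": 3.6, "restrict_hours": 3.3},
}

_DAY_BIN_LABELS = [(0, "Never 0 days"), (2, "Sometimes 1–2 days"),
                   (4, "Approx. half 3–4 days"), (6, "Most of the time 5–6 days"),
                   (7, "Always 7 days")]
_EASE_LABELS = ["Extremely difficult", "Somewhat difficult",
                "Neither easy nor difficult", "Somewhat easy", "Extremely easy"]
_RESTRICT_EDGES = [(0.5, "<0.5 h"), (1.05, "0.5–1 h"), (2.05, "1.1–2 h"),
                   (3.05, "2.1–3 h"), (4.0, "3.1–4 h"), (np.inf, ">4 h")]


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    Defaults emulate the shape of the trial this package analyses: 8 TRE +
    8 control participants, a 14-day baseline then 35 intervention days,
    per-day true adherence probability 0.63 in the TRE arm (0.79 for
    controls keeping their >= 12 h habitual window), habitual eating
    windows of roughly 09:00-21:30, and flash-CGM physiology at a 15-min
    cadence. Clock times/durations in minutes, glucose in mmol/L.
    """

    n_tre: int = Field(8, ge=0)
    n_control: int = Field(8, ge=0)
    seed: int = 0
    adherence_p: float | dict[str, float] = 0.63
    control_adherence_p: float = Field(0.79, ge=0, le=1)
    baseline_first_mean: float = 540.0
    baseline_first_sd: float = Field(30.0, ge=0)
    baseline_last_mean: float = 1290.0
    baseline_last_sd: float = Field(30.0, ge=0)
    meals_per_day: tuple[int, int] = (3, 4)
    meal_amplitude_mean: float = 2.5
    meal_amplitude_sd: float = Field(0.5, ge=0)
    meal_amplitude_range: tuple[float, float] = (2.0, 4.5)
    meal_tau: float = Field(45.0, gt=0)
    meal_duration: float = Field(180.0, gt=0)
    basal_glucose: float = Field(5.0, gt=0)
    circadian_amplitude: float = Field(0.3, ge=0)
    dawn_bump_amplitude: float = Field(0.5, ge=0)
    wake_time: float = 420.0
    noise_sd: float = Field(0.2, ge=0)
    sensor_dropout_p: float = Field(0.05, ge=0, le=1)
    cadence: int = Field(15, gt=0)
    baseline_days: int = Field(14, ge=1)
    intervention_days: int = Field(35, ge=1)
    start_date: dt.date = dt.date(2022, 2, 14)
    violation_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        probs = (self.adherence_p.values()
                 if isinstance(self.adherence_p, dict) else [self.adherence_p])
        for p in probs:
            if not 0 <= p <= 1:
                raise ValueError("adherence_p must lie in [0, 1]")
        if abs(sum(self.violation_mix) - 1) > 1e-9:
            raise ValueError("violation_mix must sum to 1")
        return self

    def p_adherent(self, day: int) -> float:
        """TRE behavioural adherence probability for intervention day."""
        if isinstance(self.adherence_p, dict):
            return self.adherence_p["W2"] if day <= 14 else self.adherence_p["W5"]
        return self.adherence_p

    @property
    def intervention_start(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.baseline_days)

    def date_of_day(self, day: int) -> dt.date:
        """Calendar date of a study day (day 1 = first intervention day)."""
        return self.intervention_start + dt.timedelta(days=day - 1)


@dataclass(frozen=True)
class GroundTruth:
    """Behavioural truth of one participant-day."""

    participant: str
    day: int
    true_adherent: bool
    true_meal_times: tuple[float, ...]
    violation_type: str  # "", "early", "late", "unreported"

    @property
    def unreported_intake(self) -> bool:
        return self.violation_type == "unreported"


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: frames in the pipeline's file dialects."""

    config: SimulationConfig
    roster: pd.DataFrame
    diary: pd.DataFrame
    cgm: dict[str, pd.DataFrame]
    questionnaire: pd.DataFrame
    ground_truth: pd.DataFrame
    truths: list[GroundTruth] = field(default_factory=list)


def _grid(value: float, cadence: float) -> float:
    return round(value / cadence) * cadence


def simulate_glucose_day(meal_times, config: SimulationConfig,
                         seed: int | np.random.Generator):
    """One eating day of CGM samples (04:00-04:00).

    Returns ``(minutes, glucose)`` with minutes on the eating-day scale
    (240 .. 1680) at the configured cadence. Glucose is basal + circadian
    sine (24 h period, trough ~03:00) + a Gaussian dawn rise at wake +
    one gamma-like kernel per meal, ``A * (dt/tau) * exp(1 - dt/tau)``
    truncated at ``meal_duration`` (peak = A at dt = tau), + N(0, noise_sd)
    sensor noise. ``meal_times`` may be bare minutes or (minute, amplitude)
    pairs; bare times get amplitudes drawn from the configured truncated
    normal. Deterministic under a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.arange(EATING_DAY_START, EATING_DAY_START + DAY_MINUTES,
                  config.cadence, dtype=float)
    g = np.full_like(t, config.basal_glucose)
    # trough at 03:00: sin phase -pi/2 at t = 180
    g += config.circadian_amplitude * np.sin(2 * np.pi * (t - 540.0) / DAY_MINUTES)
    g += config.dawn_bump_amplitude * np.exp(
        -0.5 * ((t - config.wake_time) / 30.0) ** 2)
    for meal in meal_times:
        if isinstance(meal, (tuple, list)):
            m, amp = meal
        else:
            m, amp = meal, _draw_amplitude(rng, config)
        delta = t - m
        mask = (delta >= 0) & (delta <= config.meal_duration)
        x = delta[mask] / config.meal_tau
        g[mask] += amp * x * np.exp(1 - x)
    if config.noise_sd > 0:
        g += rng.normal(0.0, config.noise_sd, size=len(t))
    return t, np.maximum(g, 0.1)


def _draw_amplitude(rng: np.random.Generator, config: SimulationConfig) -> float:
    lo, hi = config.meal_amplitude_range
    while True:
        a = rng.normal(config.meal_amplitude_mean, config.meal_amplitude_sd)
        if lo <= a <= hi:
            return float(a)


def _draw_habitual(rng: np.random.Generator,
                   config: SimulationConfig) -> tuple[float, float]:
    """Habitual first/last times on the grid, window in [12 h, 14.5 h].

    The lower bound is the trial's eligibility floor; the upper bound
    keeps the 3 h-reduced target window (plus the 30-min allowance) inside
    the 12 h ceiling, so the generator's adherent days are consistently
    adherent under every sub-criterion.
    """
    while True:
        first = _grid(rng.normal(config.baseline_first_mean,
                                 config.baseline_first_sd), config.cadence)
        last = _grid(rng.normal(config.baseline_last_mean,
                                config.baseline_last_sd), config.cadence)
        if 720 <= last - first <= 870:
            return first, last


def _middle_meals(rng: np.random.Generator, first: float, last: float,
                  n_middle: int, config: SimulationConfig) -> list[float]:
    """Meal times strictly between first and last, separated by
    ``meal_duration`` plus one hour from each other and from the endpoints,
    so each meal's excursion rises from a fully decayed baseline and stands
    alone. Fewer middles are placed when the window cannot hold them."""
    sep = config.meal_duration + 60.0
    out: list[float] = []
    candidates = np.arange(first + sep, last - sep + 1, config.cadence)
    for _ in range(n_middle):
        ok = [c for c in candidates
              if all(abs(c - m) >= sep for m in out)]
        if not ok:
            break
        out.append(float(rng.choice(ok)))
    return sorted(out)


def _day_meals(rng: np.random.Generator, first: float, last: float,
               config: SimulationConfig) -> list[float]:
    lo, hi = config.meals_per_day
    n = int(rng.integers(lo, hi + 1))
    return [first] + _middle_meals(rng, first, last, max(n - 2, 0), config) + [last]


_CATEGORY_BY_POSITION = {0: "breakfast", -1: "dinner"}


def simulate_participant(config: SimulationConfig, group: Group,
                         seed: int | np.random.Generator,
                         participant_id: str = "P01"):
    """Simulate one participant's diary, CGM trace and ground truth.

    Returns ``(diary_df, cgm_df, truths, targets)`` where the frames are in
    the file dialects the readers consume and ``truths`` is one
    :class:`GroundTruth` per study day. Baseline days keep the habitual
    (>= 12 h) window; each TRE intervention day is behaviourally adherent
    with the configured probability, otherwise violated by an early first
    intake, a late last intake, or an unreported late-evening meal present
    only in the CGM trace. Sensor-dropout days emit no CGM samples.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cad = config.cadence
    hab_first, hab_last = _draw_habitual(rng, config)
    targets = derive_protocol_targets(hab_first, hab_last)

    diary_rows: list[dict] = []
    cgm_rows: list[dict] = []
    truths: list[GroundTruth] = []

    days = range(1 - config.baseline_days, config.intervention_days + 1)
    for day in days:
        date = config.date_of_day(day)
        violation = ""
        unreported_time: float | None = None

        # day-to-day variability slides the whole window by up to one grid
        # step; the window length itself stays put, so a behaviourally
        # adherent day satisfies every sub-criterion by construction
        slide = cad * rng.integers(-1, 2)
        if day <= 0 or group is Group.CONTROL:
            first = hab_first + slide
            last = hab_last + slide
            if day <= 0 or rng.random() < config.control_adherence_p:
                true_adherent = True
            else:
                # control lapse: window shrunk below 12 h
                first += (hab_last - hab_first - 720) + cad * rng.integers(1, 9)
                true_adherent = False
                violation = "shrunk"
        else:
            first = targets.target_first + slide
            last = targets.target_last + slide
            if rng.random() < config.p_adherent(day):
                true_adherent = True
            else:
                true_adherent = False
                violation = ("early", "late", "unreported")[
                    rng.choice(3, p=list(config.violation_mix))]
                if violation == "early":
                    first = targets.target_first - cad * rng.integers(3, 9)
                elif violation == "late":
                    last = targets.target_last + cad * rng.integers(3, 9)
                else:
                    # present in the CGM trace, absent from the diary; far
                    # enough past dinner that its excursion stands alone and
                    # still fits inside the eating day
                    unreported_time = last + cad * rng.integers(14, 18)

        meals = _day_meals(rng, first, last, config)
        for pos, m in enumerate(meals):
            category = ("breakfast" if pos == 0 else
                        "dinner" if pos == len(meals) - 1 else
                        ("lunch", "snack")[rng.integers(0, 2)])
            diary_rows.append(_diary_row(participant_id, date, m, category,
                                         item=category, caloric=True))
        # a permitted fasting drink before the window opens
        diary_rows.append(_diary_row(participant_id, date,
                                     max(first - 60.0 * rng.integers(1, 4),
                                         EATING_DAY_START + 60.0),
                                     "drink", item="black coffee",
                                     caloric=False))

        cgm_meals = list(meals)
        if unreported_time is not None:
            cgm_meals.append(unreported_time)
        if rng.random() >= config.sensor_dropout_p:
            minutes, glucose = simulate_glucose_day(cgm_meals, config, rng)
            midnight = dt.datetime.combine(date, dt.time(0, 0))
            for m, g in zip(minutes, glucose):
                cgm_rows.append({
                    "participant": participant_id,
                    "timestamp": (midnight + dt.timedelta(minutes=float(m)))
                    .strftime("%Y-%m-%d %H:%M"),
                    "glucose_mmol_l": round(float(g), 2),
                })

        truths.append(GroundTruth(
            participant=participant_id, day=day,
            true_adherent=true_adherent,
            true_meal_times=tuple(cgm_meals),
            violation_type=violation,
        ))

    diary_df = pd.DataFrame(
        diary_rows,
        columns=["participant", "date", "time", "category", "item", "caloric"])
    cgm_df = pd.DataFrame(
        cgm_rows, columns=["participant", "timestamp", "glucose_mmol_l"])
    return diary_df, cgm_df, truths, targets


def _diary_row(participant: str, eating_day: dt.date, minutes: float,
               category: str, item: str, caloric: bool) -> dict:
    # times past 24:00 roll onto the next calendar date in the file
    date, m = eating_day, minutes
    if m >= DAY_MINUTES:
        date, m = date + dt.timedelta(days=1), m - DAY_MINUTES
    return {"participant": participant, "date": date.isoformat(),
            "time": format_clock(m), "category": category,
            "item": item, "caloric": str(caloric).lower()}


def _questionnaire_rows(rng: np.random.Generator, participant: str,
                        group: Group) -> list[dict]:
    centers = _QUESTIONNAIRE_CENTERS[group]
    rows = []
    for item, center in centers.items():
        if item == "ease":
            level = int(np.clip(round(rng.normal(center, 1.0)), 1, 5))
            category = _EASE_LABELS[level - 1]
        elif item == "realistic_days":
            category = str(int(np.clip(round(rng.normal(center, 1.5)), 0, 7)))
        elif item == "restrict_hours":
            hours = rng.normal(center, 0.8)
            category = next(lab for edge, lab in _RESTRICT_EDGES if hours <= edge)
        else:
            days = int(np.clip(round(rng.normal(center, 1.2)), 0, 7))
            category = next(lab for edge, lab in _DAY_BIN_LABELS if days <= edge)
        rows.append({"participant": participant, "group": group.value,
                     "item": item, "category": category})
    return rows


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Simulate the full cohort: roster, diaries, CGM, questionnaire, truth.

    A single master seed spawns independent per-participant substreams, so
    the cohort is reproducible and participants are independent.
    """
    ss = np.random.SeedSequence(config.seed)
    n = config.n_tre + config.n_control
    streams = ss.spawn(n + 1)

    ids = ([f"TRE{i + 1:02d}" for i in range(config.n_tre)]
           + [f"CTL{i + 1:02d}" for i in range(config.n_control)])
    groups = ([Group.TRE] * config.n_tre + [Group.CONTROL] * config.n_control)

    roster_rows, diary_frames, truths_all, gt_rows, q_rows = [], [], [], [], []
    cgm: dict[str, pd.DataFrame] = {}
    for pid, group, stream in zip(ids, groups, streams[:n]):
        rng = np.random.default_rng(stream)
        diary_df, cgm_df, truths, targets = simulate_participant(
            config, group, rng, pid)
        diary_frames.append(diary_df)
        cgm[pid] = cgm_df
        truths_all.extend(truths)
        gt_rows.extend({"participant": t.participant, "day": t.day,
                        "true_adherent": t.true_adherent,
                        "violation_type": t.violation_type} for t in truths)
        # one male among the controls mirrors the cohort's 15:1 sex ratio
        sex = "M" if (group is Group.CONTROL and pid.endswith("01")) else "F"
        roster_rows.append({
            "id": pid, "group": group.value, "sex": sex,
            "age": int(rng.integers(19, 47)),
            "weight": round(float(rng.normal(66.5, 10.0)), 1),
            "bmi": round(float(np.clip(rng.normal(23.5, 2.3), 18.6, 29.8)), 1),
            "sbp": int(rng.integers(100, 136)),
            "dbp": int(rng.integers(62, 86)),
        })
        q_rows.extend(_questionnaire_rows(rng, pid, group))

    diary = (pd.concat(diary_frames, ignore_index=True) if diary_frames
             else pd.DataFrame(columns=["participant", "date", "time",
                                        "category", "item", "caloric"]))
    return CohortBundle(
        config=config,
        roster=pd.DataFrame(roster_rows, columns=["id", "group", "sex", "age",
                                                  "weight", "bmi", "sbp", "dbp"]),
        diary=diary,
        cgm=cgm,
        questionnaire=pd.DataFrame(q_rows, columns=["participant", "group",
                                                    "item", "category"]),
        ground_truth=pd.DataFrame(gt_rows, columns=["participant", "day",
                                                    "true_adherent",
                                                    "violation_type"]),
        truths=truths_all,
    )


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write every input file plus the ground truth.

    Layout: ``roster.csv``, ``diary.csv``, ``questionnaire.csv``,
    ``ground_truth.csv`` and one ``cgm/<participant>.csv`` per participant.
    Fully determined by ``config.seed``. Returns the written paths.
    """
    out = Path(out_dir)
    (out / "cgm").mkdir(parents=True, exist_ok=True)
    bundle = simulate_cohort(config)
    paths = {
        "roster": out / "roster.csv",
        "diary": out / "diary.csv",
        "questionnaire": out / "questionnaire.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    bundle.roster.to_csv(paths["roster"], index=False)
    bundle.diary.to_csv(paths["diary"], index=False)
    bundle.questionnaire.to_csv(paths["questionnaire"], index=False)
    bundle.ground_truth.to_csv(paths["ground_truth"], index=False)
    for pid, df in bundle.cgm.items():
        p = out / "cgm" / f"{pid}.csv"
        df.to_csv(p, index=False)
        paths[f"cgm/{pid}"] = p
    return paths
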