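"""End-to-end wiring: ingestion -> detection -> scoring -> summary tables.

`run_pipeline` takes a RunConfig pointing either at real input files
(roster, diary, per-participant CGM exports, questionnaire) or at a
simulation block, scores every participant-day, and writes four outputs
to the configured directory:

* ``day_adherence.csv``  — per-day criterion outcomes and adherence codes
* ``phase_summary.csv``  — group x phase mean adherence %, SEM, days/week
* ``questionnaire_summary.csv`` — per-item group means, SEM, t, p
* ``run.log``            — every threshold used, with ISO timestamps
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from . import adherence as adh
from . import cgm as cgm_mod
from . import diet_diary as diary_mod
from . import questionnaire as q_mod
from .study_model import Group, PHASES, ProtocolTargets, derive_protocol_targets
from .synthetic import SimulationConfig, simulate_study
from .timeutils import eating_day_span, format_clock, minutes_within_day

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_day", "load_config"]

log = logging.getLogger("trescore")

_Q_ITEMS = ["ease", "morning_days", "evening_days", "window_days",
            "plan_days", "realistic_days", "restrict_hours"]


class DataPaths(BaseModel):
    roster: Path
    diary: Path
    cgm: Path  # directory of <participant>.csv exports
    questionnaire: Path | None = None


class RunConfig(BaseModel):
    """Structured run configuration.

    Exactly one of ``data`` (real files) or ``simulation`` must be set.
    ``overrides`` feeds any ProtocolTargets constant (e.g. ``shift``,
    ``glucose_threshold``) for sensitivity analysis.
    """

    data: DataPaths | None = None
    simulation: SimulationConfig | None = None
    intervention_start: dt.date | None = None
    overrides: dict[str, float] = {}
    out_dir: Path = Path("trescore_out")
    seed: int = 0
    weighted_mean: bool = False
    exclude_wake_excursions: bool = False
    sleep_interval: tuple[float, float] = (1380.0, 420.0)  # 23:00-07:00
    missing_coverage: float = 0.5
    verbosity: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.data is None) == (self.simulation is None):
            raise ValueError("exactly one of 'data' or 'simulation' must be set")
        if self.data is not None and self.intervention_start is None:
            raise ValueError("'intervention_start' is required with real data")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


@dataclass
class ParticipantResult:
    participant: str
    group: Group
    targets: ProtocolTargets | None
    records: list  # (day_index, DayAdherenceRecord)
    phase_percents: dict[str, float | None] = field(default_factory=dict)
    combined: float | None = None


@dataclass
class ReportBundle:
    day_table: pd.DataFrame
    phase_table: pd.DataFrame
    questionnaire_table: pd.DataFrame | None
    participants: list[ParticipantResult]
    out_dir: Path


def _setup_logging(out_dir: Path, verbosity: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    log.handlers = [handler]
    log.setLevel(verbosity)


def _load_traces(cgm_dir: Path, roster: pd.DataFrame) -> dict[str, cgm_mod.CGMTrace | None]:
    traces: dict[str, cgm_mod.CGMTrace | None] = {}
    missing_files = []
    for pid in roster["id"]:
        path = cgm_dir / f"{pid}.csv"
        if not path.exists():
            missing_files.append(pid)
            continue
        try:
            traces[pid] = cgm_mod.read_cgm(path)
        except ValueError as exc:
            if "contains no records" in str(exc):
                log.warning("participant %s: empty CGM export (sensor never "
                            "recorded); all days will score missing", pid)
                traces[pid] = None
            else:
                raise
    if missing_files:
        raise FileNotFoundError(
            f"roster participants without a CGM export: {missing_files}")
    return traces


def score_participant(pid: str, group: Group,
                      events: list[diary_mod.DiaryEvent],
                      trace: cgm_mod.CGMTrace | None,
                      intervention_start: dt.date,
                      overrides: dict[str, float],
                      exclude_wake: bool = False,
                      sleep_interval: tuple[float, float] = (1380.0, 420.0),
                      missing_coverage: float = 0.5) -> ParticipantResult:
    """Score every W0 and intervention day of one participant.

    Baseline (W0) mean eating times derive the protocol targets; W0 days
    for both arms and all control days use the habitual >= 12 h window
    rule, TRE intervention days the full four-criterion rule with the CGM
    cross-check.
    """
    windows = diary_mod.daily_windows(events)

    def date_of(day: int) -> dt.date:
        return intervention_start + dt.timedelta(days=day - 1)

    day_of = {date_of(d): d for d in range(-13, 36)}

    w0_windows = [windows[date_of(d)] for d in PHASES["W0"].days()
                  if date_of(d) in windows]
    targets = None
    if w0_windows:
        mean_first, mean_last, _, n_days = diary_mod.mean_times(w0_windows)
        log.info("participant %s: baseline means %s-%s over %d diary days",
                 pid, format_clock(mean_first), format_clock(mean_last), n_days)
        try:
            targets = derive_protocol_targets(mean_first, mean_last, **overrides)
        except ValueError as exc:
            log.warning("participant %s: %s; TRE days cannot be scored", pid, exc)

    excursions = []
    if trace is not None and len(trace):
        excursions = cgm_mod.detect_excursions(
            trace, targets if targets is not None
            else ProtocolTargets(baseline_first=0, baseline_last=720, **overrides))
        if exclude_wake:
            excursions = cgm_mod.exclude_sleep_onsets(
                excursions, *sleep_interval)

    records = []
    for day in list(PHASES["W0"].days()) + list(range(1, 36)):
        date = date_of(day)
        window = windows.get(date)
        if group is Group.CONTROL or day <= 0:
            rec = adh.score_control_day(window, group=group, eating_day=date)
        elif targets is None:
            rec = adh.DayAdherenceRecord(eating_day=date, group=group,
                                         adherent=None, diary_available=False,
                                         cgm_available=False)
        else:
            day_events = None
            if trace is not None:
                day_events = cgm_mod.daily_glucose_events(
                    excursions, trace, date, missing_coverage=missing_coverage)
            rec = adh.score_tre_day(window, targets, day_events)
            if rec.eating_day is None:
                rec = adh.DayAdherenceRecord(
                    eating_day=date, group=group, adherent=None,
                    cgm_available=False, diary_available=False)
        records.append((day, rec))

    result = ParticipantResult(pid, group, targets, records)
    recs_by_phase = {
        label: [r for d, r in records if d in PHASES[label]]
        for label in PHASES
    }
    for label, recs in recs_by_phase.items():
        summary = adh.phase_summary(recs, PHASES[label], day_of)
        result.phase_percents[label] = summary.percent
    result.combined = adh.combine_phases(
        result.phase_percents.get("W2"), result.phase_percents.get("W5"),
        weights=None)
    return result


def _phase_table(results: list[ParticipantResult],
                 weighted: bool) -> pd.DataFrame:
    rows = []
    for group in (Group.TRE, Group.CONTROL):
        members = [r for r in results if r.group is group]
        for label in ["W0", "W2", "W5", "Mean"]:
            if label == "Mean":
                vals = [adh.combine_phases(r.phase_percents.get("W2"),
                                           r.phase_percents.get("W5"),
                                           weights=(14, 21) if weighted else None)
                        for r in members]
            else:
                vals = [r.phase_percents.get(label) for r in members]
            vals = [v for v in vals if v is not None]
            if not vals:
                rows.append({"group": group.value, "phase": label,
                             "mean_percent": float("nan"), "sem": float("nan"),
                             "days_per_week": float("nan"), "n": 0})
                continue
            mean, sem, n = adh.group_phase_summary(vals)
            rows.append({
                "group": group.value, "phase": label,
                "mean_percent": adh.round_half_up(mean, 1),
                "sem": adh.round_half_up(sem, 1) if np.isfinite(sem) else float("nan"),
                "days_per_week": adh.round_half_up(mean / 100.0 * 7.0, 1),
                "n": n,
            })
    return pd.DataFrame(rows)


def _day_table(results: list[ParticipantResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for day, r in res.records:
            rows.append({
                "participant": res.participant, "group": res.group.value,
                "day": day, "eating_day": r.eating_day,
                "criterion_window_reduced": r.criterion_window_reduced,
                "criterion_window_le_12h": r.criterion_window_le_12h,
                "criterion_times_shifted": r.criterion_times_shifted,
                "criterion_glucose_match": r.criterion_glucose_match,
                "adherent": r.adherent,
                "cgm_available": r.cgm_available,
                "diary_available": r.diary_available,
            })
    return pd.DataFrame(rows)


def _questionnaire_table(responses: list[q_mod.LikertResponse]) -> pd.DataFrame:
    rows = []
    for item in _Q_ITEMS:
        tre = [r.value for r in responses
               if r.item == item and r.group is Group.TRE]
        ctl = [r.value for r in responses
               if r.item == item and r.group is Group.CONTROL]
        if not tre and not ctl:
            continue
        row: dict = {"item": item}
        if tre:
            s = q_mod.group_summary(tre, item, Group.TRE)
            row.update(tre_mean=round(s.mean, 2), tre_sem=round(s.sem, 2)
                       if np.isfinite(s.sem) else float("nan"), tre_n=s.n)
        if ctl:
            s = q_mod.group_summary(ctl, item, Group.CONTROL)
            row.update(ctrl_mean=round(s.mean, 2), ctrl_sem=round(s.sem, 2)
                       if np.isfinite(s.sem) else float("nan"), ctrl_n=s.n)
        if len(tre) >= 2 and len(ctl) >= 2:
            t, df, p = q_mod.two_sample_t(tre, ctl, pooled=True)
            row.update(t=round(t, 3), p=round(p, 4))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full scoring run described by ``config``."""
    out_dir = Path(config.out_dir)
    _setup_logging(out_dir, config.verbosity)

    if config.simulation is not None:
        sim = config.simulation.model_copy(update={"seed": config.seed})
        data_dir = out_dir / "data"
        log.info("simulating cohort: n_tre=%d n_control=%d seed=%d",
                 sim.n_tre, sim.n_control, sim.seed)
        simulate_study(sim, data_dir)
        paths = DataPaths(roster=data_dir / "roster.csv",
                          diary=data_dir / "diary.csv",
                          cgm=data_dir / "cgm",
                          questionnaire=data_dir / "questionnaire.csv")
        intervention_start = sim.intervention_start
    else:
        paths = config.data
        intervention_start = config.intervention_start

    probe = ProtocolTargets(baseline_first=0, baseline_last=720,
                            **config.overrides)
    log.info("thresholds: shift=%.0fmin window_tolerance=%.0fmin "
             "required_reduction=%.0fmin max_window=%.0fmin "
             "glucose_threshold=%.2fmmol/L min_elevation_duration=%.0fmin "
             "glucose_match_tolerance=%.0fmin intervention_days=%d "
             "missing_coverage=%.2f weighted_mean=%s "
             "exclude_wake_excursions=%s sleep_interval=%s-%s seed=%d",
             probe.shift, probe.window_tolerance, probe.required_reduction,
             probe.max_window, probe.glucose_threshold,
             probe.min_elevation_duration, probe.glucose_match_tolerance,
             probe.intervention_days, config.missing_coverage,
             config.weighted_mean, config.exclude_wake_excursions,
             format_clock(config.sleep_interval[0]),
             format_clock(config.sleep_interval[1]), config.seed)

    roster = pd.read_csv(paths.roster, dtype={"id": str})
    all_events = diary_mod.read_diary(paths.diary)
    diary_ids = {e.participant for e in all_events}
    roster_ids = set(roster["id"])
    orphans = sorted(diary_ids - roster_ids)
    if orphans:
        raise ValueError(f"diary participants not in roster: {orphans}")
    traces = _load_traces(Path(paths.cgm), roster)

    results = []
    for _, row in roster.iterrows():
        pid, group = row["id"], Group(row["group"])
        events = [e for e in all_events if e.participant == pid]
        results.append(score_participant(
            pid, group, events, traces.get(pid), intervention_start,
            config.overrides, config.exclude_wake_excursions,
            config.sleep_interval, config.missing_coverage))

    day_table = _day_table(results)
    phase_table = _phase_table(results, config.weighted_mean)
    day_table.to_csv(out_dir / "day_adherence.csv", index=False)
    phase_table.to_csv(out_dir / "phase_summary.csv", index=False)

    q_table = None
    if paths.questionnaire is not None and Path(paths.questionnaire).exists():
        responses = q_mod.read_responses(paths.questionnaire)
        q_table = _questionnaire_table(responses)
        q_table.to_csv(out_dir / "questionnaire_summary.csv", index=False)

    log.info("run complete: %d participants, outputs in %s",
             len(results), out_dir)
    return ReportBundle(day_table=day_table, phase_table=phase_table,
                        questionnaire_table=q_table, participants=results,
                        out_dir=out_dir)


def render_day(trace: cgm_mod.CGMTrace,
               window: diary_mod.EatingWindow | None,
               targets: ProtocolTargets,
               eating_day: dt.date,
               path: str | Path | None = None) -> dict:
    """Diagnostic one-day view: glucose curve, reported first/last intake
    markers, shaded target window, detected excursion onsets.

    Returns the marker coordinates (minutes on the eating-day scale) so
    callers and tests can assert on them; optionally writes the figure.
    Raises when the day has no CGM samples.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    start, end = eating_day_span(eating_day)
    mask = (trace.times >= start) & (trace.times < end)
    if not mask.any():
        raise ValueError(f"no CGM samples on {eating_day}")
    sub = cgm_mod.CGMTrace(trace.participant, trace.times[mask],
                           trace.glucose[mask], trace.nominal_cadence)
    excursions = cgm_mod.detect_excursions(sub, targets)
    minutes = np.array([minutes_within_day(ts.to_pydatetime(), eating_day)
                        for ts in sub.times])
    onsets = [minutes_within_day(e.onset, eating_day) for e in excursions]

    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.plot(minutes / 60.0, sub.glucose, lw=1.2, color="tab:blue",
            label="glucose")
    ax.axvspan(targets.target_first / 60.0, targets.target_last / 60.0,
               color="tab:green", alpha=0.15, label="target window")
    markers = {"onsets": onsets, "target_first": targets.target_first,
               "target_last": targets.target_last}
    if window is not None:
        for x, lab in ((window.first_intake, "reported first"),
                       (window.last_intake, "reported last")):
            ax.axvline(x / 60.0, color="tab:red", ls="--", lw=1.0)
        markers.update(reported_first=window.first_intake,
                       reported_last=window.last_intake)
    for x in onsets:
        ax.plot(x / 60.0, np.interp(x, minutes, sub.glucose), "v",
                color="black", ms=7)
    ax.set_xlabel("clock time (h, eating day)")
    ax.set_ylabel("glucose (mmol/L)")
    ax.set_title(f"{trace.participant} {eating_day}")
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return markers
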