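"""Exit-questionnaire coding and group comparison.

Responses arrive as verbatim Likert option text per item. Day-frequency
items ("On how many days of the week ...") are coded to the midpoint of
their printed bin (Never 0 / Sometimes 1-2 / Approx. half 3-4 / Most of
the time 5-6 / Always 7); the ease item to 1-5; the realistic-days item
accepts integers 0-7 directly; the window-restriction item maps its six
duration bins to an ordinal 1-6. Summaries report group mean +/- SEM and
a two-sample t-test; the sex-ratio comparison uses a 2x2 chi-squared.

The t and chi-squared statistics are computed from their closed forms
here; scipy serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .adherence import round_half_up
from .study_model import Group

__all__ = [
    "LikertResponse",
    "GroupItemSummary",
    "read_responses",
    "code_likert",
    "days_to_percent",
    "group_summary",
    "two_sample_t",
    "chi_square_2x2",
    "ITEM_CODINGS",
]

_DAY_BINS = {
    "Never 0 days": 0.0,
    "Sometimes 1–2 days": 1.5,
    "Approx. half 3–4 days": 3.5,
    "Most of the time 5–6 days": 5.5,
    "Always 7 days": 7.0,
}

_EASE = {
    "Extremely difficult": 1.0,
    "Somewhat difficult": 2.0,
    "Neither easy nor difficult": 3.0,
    "Somewhat easy": 4.0,
    "Extremely easy": 5.0,
}

_RESTRICT_HOURS = {
    "<0.5 h": 1.0,
    "0.5–1 h": 2.0,
    "1.1–2 h": 3.0,
    "2.1–3 h": 4.0,
    "3.1–4 h": 5.0,
    ">4 h": 6.0,
}

#: item id -> category->value map; day-frequency items share the bin
#: midpoints, realistic_days is numeric 0-7. Config-replaceable: pass a
#: custom map to code_likert for sensitivity to the coding choice.
ITEM_CODINGS: dict[str, dict[str, float]] = {
    "ease": _EASE,
    "morning_days": _DAY_BINS,
    "evening_days": _DAY_BINS,
    "window_days": _DAY_BINS,
    "plan_days": _DAY_BINS,
    "restrict_hours": _RESTRICT_HOURS,
}


@dataclass(frozen=True)
class LikertResponse:
    participant: str
    group: Group
    item: str
    category: str
    value: float


@dataclass(frozen=True)
class GroupItemSummary:
    item: str
    group: Group
    n: int
    mean: float
    sem: float  # NaN when n < 2 (undefined)


def read_responses(path) -> list[LikertResponse]:
    """Read a ``participant,group,item,category`` responses file, coding
    each category as it is parsed."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"participant", "group", "item", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"responses file {path} lacks columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            value = code_likert(row["item"], row["category"])
        except ValueError as exc:
            raise ValueError(f"line {idx + 2}: {exc}") from None
        out.append(LikertResponse(participant=row["participant"],
                                  group=Group(row["group"]),
                                  item=row["item"],
                                  category=row["category"],
                                  value=value))
    return out


def code_likert(item: str, category: str,
                codings: dict[str, dict[str, float]] | None = None) -> float:
    """Numeric coding of one response category.

    Day bins go to interval midpoints, ease to 1-5, restriction bins to an
    ordinal 1-6; ``realistic_days`` answers are plain integers 0-7.
    """
    codings = ITEM_CODINGS if codings is None else codings
    text = category.strip()
    if item == "realistic_days":
        try:
            value = float(text)
        except ValueError:
            raise ValueError(
                f"item 'realistic_days': answer {category!r} is not a number"
            ) from None
        if not 0 <= value <= 7 or value != int(value):
            raise ValueError(
                f"item 'realistic_days': answer {category!r} outside 0–7")
        return value
    if item not in codings:
        raise ValueError(f"unknown questionnaire item {item!r}")
    # tolerate plain hyphens for the en-dash ranges in option text
    table = {k.replace("–", "-"): v for k, v in codings[item].items()}
    key = text.replace("–", "-")
    if key not in table:
        raise ValueError(f"item {item!r}: unknown category {category!r}")
    return table[key]


def days_to_percent(days: float) -> int:
    """Days-per-week as a rounded-half-up integer percent of the week."""
    if not 0 <= days <= 7:
        raise ValueError(f"days-per-week {days} outside [0, 7]")
    return int(round_half_up(100.0 * days / 7.0))


def group_summary(values: list[float], item: str,
                  group: Group) -> GroupItemSummary:
    """Mean and SEM (sample sd over sqrt(n)) of one item within one group.

    With a single respondent the mean is reported and the SEM flagged
    undefined (NaN).
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        raise ValueError(f"no responses for item {item!r} in group {group}")
    sem = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
           if len(vals) > 1 else float("nan"))
    return GroupItemSummary(item=item, group=group, n=len(vals),
                            mean=float(vals.mean()), sem=sem)


def two_sample_t(a: list[float], b: list[float],
                 pooled: bool = True) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test.

    Student's pooled-variance form by default (the convention of the SPSS
    output the trial reports); ``pooled=False`` gives Welch's unequal-
    variance form. Returns (t, df, p). Two groups with zero variance and
    equal means give t = 0, p = 1 by convention.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    if pooled:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        sea2, seb2 = va / na, vb / nb
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (sea2 ** 2 / (na - 1) + seb2 ** 2 / (nb - 1))
    t = diff / se
    p = 2.0 * _stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(table, correction: bool = False):
    """Pearson chi-squared on a 2x2 count table.

    No continuity correction by default; ``correction=True`` applies
    Yates'. A zero row or column total leaves the statistic undefined and
    returns (nan, 1, nan) rather than raising.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi_square_2x2 needs a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return float("nan"), 1, float("nan")
    expected = np.outer(rows, cols) / total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev ** 2 / expected).sum())
    p = float(_stats.chi2.sf(statistic, 1))
    return statistic, 1, p
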