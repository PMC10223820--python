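"""Shared test utilities: trace builders and the brute-force excursion oracle."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from trescore.cgm import CGMTrace

DAY = dt.date(2022, 3, 1)
MIDNIGHT = dt.datetime.combine(DAY, dt.time(0))


def make_trace(minutes, glucose, participant="P01", cadence=15.0,
               midnight=MIDNIGHT) -> CGMTrace:
    """Build a trace from minutes-past-midnight and glucose arrays."""
    times = pd.DatetimeIndex(
        [midnight + dt.timedelta(minutes=float(m)) for m in minutes])
    return CGMTrace(participant=participant, times=times,
                    glucose=np.asarray(glucose, dtype=float),
                    nominal_cadence=cadence)


def brute_force_excursions(trace: CGMTrace, threshold: float = 1.0,
                           min_duration: float = 60.0,
                           ref_window: float = 30.0,
                           max_gap: float = 30.0):
    """Independent excursion finder: scan every (start, end) sample pair
    and check the elevation predicate directly.

    Returns a list of (onset_idx, end_idx, reference) after merging
    overlapping/abutting qualifying stretches, for comparison against the
    production detector.
    """
    t = trace.minutes()
    g = trace.glucose
    n = len(t)

    def reference(i):
        vals = [g[k] for k in range(n) if t[i] - ref_window <= t[k] < t[i]]
        return min(vals) if vals else None

    def qualifies(i, j, ref):
        if t[j] - t[i] < min_duration:
            return False
        for k in range(i, j + 1):
            if g[k] < ref + threshold:
                return False
        for k in range(i + 1, j + 1):
            if t[k] - t[k - 1] > max_gap:
                return False
        return True

    stretches = []
    for i in range(n):
        ref = reference(i)
        if ref is None:
            continue
        best_j = None
        for j in range(i, n):
            if qualifies(i, j, ref):
                best_j = j
        if best_j is not None:
            stretches.append((i, best_j, ref))

    merged = []
    for i, j, ref in stretches:
        if merged and t[i] - t[merged[-1][1]] <= trace.nominal_cadence:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], j), prev[2])
        else:
            merged.append((i, j, ref))
    return merged


def random_trace(rng: np.random.Generator, max_samples: int = 200) -> CGMTrace:
    """Random trace with step changes, gaps and threshold-grazing levels."""
    n_grid = int(rng.integers(8, max_samples + 1))
    minutes = np.arange(n_grid) * 15.0
    if rng.random() < 0.3:  # irregular offsets to graze the 30-min gap rule
        minutes = minutes + rng.choice([0.0, 5.0], size=n_grid)
        minutes = np.maximum.accumulate(minutes + np.arange(n_grid) * 1e-3)
    keep = rng.random(n_grid) > 0.15
    keep[0] = True
    minutes = minutes[keep]
    n = len(minutes)
    # piecewise-constant levels quantized to 0.5 mmol/L hit exact-threshold ties
    levels = 4.0 + 0.5 * rng.integers(0, 7, size=max(n // int(rng.integers(2, 9)) + 1, 1))
    glucose = np.repeat(levels, int(np.ceil(n / len(levels))))[:n]
    if rng.random() < 0.5:
        glucose = glucose + np.round(rng.normal(0, 0.3, size=n), 2)
    glucose = np.maximum(glucose, 0.5)
    return make_trace(minutes, glucose)


def assert_same_excursions(trace, excursions, oracle_stretches):
    """Compare production excursions against oracle (idx, idx, ref) tuples."""
    t = trace.minutes()
    got = [((e.onset - trace.times[0].to_pydatetime()).total_seconds() / 60,
            (e.end - trace.times[0].to_pydatetime()).total_seconds() / 60)
           for e in excursions]
    want = [(t[i] - t[0], t[j] - t[0]) for i, j, _ in oracle_stretches]
    assert len(got) == len(want), f"{got} != {want}"
    for (go, ge), (wo, we) in zip(got, want):
        assert abs(go - wo) < 1e-6 and abs(ge - we) < 1e-6, f"{got} != {want}"
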