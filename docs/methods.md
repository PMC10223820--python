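# Methods

## Scope and model

`trescore` scores adherence to a symmetric time-restricted-eating (TRE)
protocol: participants reduce their habitual eating window by 3 h, by
delaying first energy intake and advancing last energy intake 1.5 h each
relative to their baseline mean eating times, with a ±30 min allowance.
Adherence is assessed per 24 h period from two streams: a time-stamped
diet diary (subjective) and a continuous glucose monitor at a nominal
15-min cadence (objective). Controls keep their habitual ≥ 12 h window.

### Clock-time convention

All clock times are minutes since midnight of the *eating day*, a
wake-to-wake span fixed at 04:00–04:00 local. Intake logged between
midnight and 04:00 belongs to the previous day's window and is
represented past 24:00 (01:30 → 25:30). Because eating times then occupy
one contiguous span far from the cut, plain arithmetic means of clock
times are valid and no circular statistics are needed.

### Excursion detection

An eating occasion is detected as a sustained glucose elevation. For each
candidate onset sample, the pre-rise reference is the minimum glucose over
the preceding 30 min; a short local reference tracks slow circadian drift
without absorbing the meal rise itself. An excursion is a run of samples
at or above reference + 1 mmol/L lasting ≥ 60 min, with no sample below
the level and no gap longer than 30 min (a longer hole cannot certify
"elevated for an hour"); a candidate right after such a hole, or at the
trace start, has no reference and is skipped. Overlapping or abutting
runs merge into one excursion. Waking (dawn) excursions are *not*
excluded by default — the scoring rules never exclude them — but an
opt-in switch (`--exclude-wake-excursions`) suppresses onsets inside a
configurable sleep interval (default 23:00–07:00).

The detector is validated against a brute-force oracle that scans every
(start, end) sample pair and re-checks the elevation predicate directly,
on hundreds of randomized traces with gaps, irregular cadence and
threshold-grazing levels.

### Day scoring

A TRE intervention day is adherent iff all four sub-criteria hold:

1. window reduced from the baseline mean by ≥ 3 h − 30 min;
2. window ≤ 12 h (stored separately from 1., since a > 15 h baseline
   could satisfy a perfect 3 h reduction yet exceed 12 h);
3. first and last reported intakes within ±30 min of the shifted targets;
4. first and last detected glucose onsets within ±30 min of the reported
   first and last intake times.

The single ±30 min allowance backs both the window-reduction slack and
the time-match tolerances, so one configuration knob keeps them
consistent. Days without usable CGM (coverage below a configurable 0.5 of
expected samples) or without diary data are coded *missing*, not
non-adherent, and drop out of the denominator: adherence % =
100 × adherent ÷ available days. Baseline (W0) days — where no shifted
targets exist — and all control days use the habitual-window rule:
adherent iff the reported window is ≥ 12 h.

Phase rates use W0 = last 7 baseline days, W2 = intervention days 1–14,
W5 = days 15–35. The overall intervention rate is the unweighted mean of
the W2 and W5 rates, which is how such summaries are conventionally
printed; a day-weighted variant (weights 14 : 21) is available via
`--weighted-mean`. Report tables round percentages and days-per-week to
one decimal, half-up.

### Questionnaire coding

Day-frequency Likert items ("Never 0 days / Sometimes 1–2 / Approx. half
3–4 / Most of the time 5–6 / Always 7") are coded to bin midpoints
(0, 1.5, 3.5, 5.5, 7); the ease item to 1–5; free integer day counts 0–7
pass through; the window-restriction item maps its six duration bins to
an ordinal 1–6. The coding map is replaceable, since respondents who
report exact day counts would support finer coding than midpoints.
Days-per-week convert to percent of week by round-half-up(100·d/7).
Group summaries report mean ± SEM (sample SD over √n). The two-sample
*t*-statistic (Student pooled by default, Welch by flag) and the 2×2
Pearson chi-squared (no continuity correction by default) are computed
from their closed forms, with scipy as an independent cross-check in the
test suite.

## Synthetic cohort

The generator emulates the three input streams for a 8 + 8 cohort over a
14-day baseline and 35 intervention days, with known per-day ground
truth. Key defaults (all configurable through `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| habitual first/last intake | 09:00 ± 30 min / 21:30 ± 30 min | ~12.5 h habitual window, redrawn into [12 h, 14.5 h] so the 3 h-reduced target plus the 30-min allowance stays ≤ 12 h |
| per-day TRE adherence `adherence_p` | 0.63 | the headline adherence scale the pipeline is meant to recover; per-phase values accepted |
| control adherence | 0.79 | controls keeping a ≥ 12 h window most days |
| meals per day | 3–4, ≥ 4 h apart | main meals spaced so each excursion rises from a fully decayed baseline |
| meal amplitude | N(2.5, 0.5²) mmol/L on [2.0, 4.5] | typical postprandial CGM rises; the floor is threshold + 1 mmol/L, since the scoring model itself assumes eating occasions are detectable, and kernel analysis shows amplitudes ≲ 1.55 mmol/L cannot put the first on-grid sample over the threshold at the 15-min cadence |
| kernel time-to-peak τ | 45 min | gamma-like kernel A·(Δt/τ)·e^(1−Δt/τ), smooth, positive, parameter-sparse; truncated at 180 min |
| basal glucose | 5.0 mmol/L | normoglycemic fasting level |
| circadian amplitude / dawn bump | 0.3 / 0.5 mmol/L | sub-threshold rhythms; the dawn rise at 07:00 deliberately mimics (but does not trigger) a waking excursion |
| sensor noise | N(0, 0.2²) mmol/L | flash-CGM short-term noise |
| day-level sensor dropout | 0.05 | occasional whole-day sensor failures, exercising the denominator recalculation |

Times are drawn on the 15-min grid: self-reported diary times are
quarter-hour rounded in practice, and the simulated sensor samples on the
same nominal grid. Day-to-day variability *slides* the whole eating
window by up to one grid step rather than resizing it, so a behaviourally
adherent day satisfies the window-reduction criterion by construction
rather than straddling its tolerance boundary.

Non-adherent days are violated in equal thirds (configurable): first
intake 45–120 min early; last intake 45–120 min late; or an *unreported*
late-evening meal 210–255 min after the reported last intake, present in
the CGM trace but absent from the diary. The unreported offset range is
chosen so the extra excursion neither merges with the dinner excursion
(which stays elevated up to ~180 min at the amplitude cap) nor runs past
the end of the eating day. A diary is written for every study day; the
scoring needs per-day windows, and restricting recording to assessment
sub-windows would only thin identical data. One master seed spawns
independent per-participant substreams; cohorts are byte-reproducible.

Questionnaire responses are drawn around per-group central values chosen
to mirror the scale of real exit-questionnaire summaries (e.g. TRE
morning compliance ≈ 4.9 d/week vs control anticipation ≈ 3.4); they
exercise the coding and comparison machinery but encode no per-day truth.

### What the generator does not model

Insulin dynamics, meal-composition effects (low-carbohydrate meals that
produce no excursion), sensor drift and compression artefacts,
participant-specific chronotypes, and correlated day-to-day behaviour.
Passing recovery tests therefore show the *scoring logic* is unbiased
under the stated generative assumptions, not that detection is robust to
every physiological confounder of real traces.

## Numerical choices and edge cases

- Duplicate CGM timestamps collapse to their mean; non-positive glucose
  rows are rejected with line numbers.
- A day with no caloric diary events is "no diary data" (missing), which
  is distinct from a single-occasion zero-length window.
- `adherence_percent` of zero available days is undefined (`None`), never
  reported as 0.
- Percent/days-per-week rounding is half-up (ties away from zero) to one
  decimal, matching how trial tables are printed; all comparisons in the
  scoring itself use unrounded values.
- Tolerance comparisons are inclusive (≤), so a value exactly on a
  boundary counts as within tolerance.
- Zero-variance equal-mean groups give t = 0, p = 1 by convention; a 2×2
  table with a zero margin yields an undefined (NaN) chi-squared rather
  than an error.

## Validation summary

The test suite checks, among others: detector equivalence with the
brute-force oracle; vertical-shift invariance of detection; exact 100% /
0% end-to-end scores for noiseless always/never-adherent cohorts;
end-to-end recovery of the simulated adherence rate within the 95%
binomial interval across 20 replicate cohorts; ≥ 95% meal-onset
localization within one cadence step on single-meal days; and ≥ 90%
capture of unreported-intake violations by the objective criterion while
the diary-only criteria pass. Problem sizes (8 + 8 × 35 days, 20
replicates, 500 single-meal days, 300 random oracle traces) were chosen
as the smallest that exercise the stated properties with stable margins.

## Known limitations

- The ≤ 12 h clause and the 3 h-reduction clause can genuinely conflict
  for baselines over 15 h; both booleans are stored so such days are
  auditable, but the conjunction is what scores.
- Excursion onsets are reported at sample resolution (15 min); no
  sub-sample interpolation is attempted.
- The unweighted W2/W5 combination weights a 14-day phase equally with a
  21-day phase; use `--weighted-mean` when a day-weighted rate is wanted.
- Control adherence uses the diary alone; CGM is not consulted for
  controls, so unreported control-arm eating is invisible by design.
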