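# Methods

## Scoring model

The score is a sum of independent per-element sub-scores over value bands.
Band lookup happens in *rounded* value space: heart rate, systolic pressure
and respiratory rate are rounded to integers and temperature to 0.1 °C
(half away from zero) before lookup, which is what a nurse reading the
printed card does and which makes the printed bands — "40–50" followed by
"51–100" — exhaustive and disjoint. The card's asymmetries are implemented
literally: systolic pressure above 200 mmHg scores 2 (there is no high-side
3), fever never scores above 1, and bradypnoea below 9/min scores 2. We
deliberately do not "correct" these toward other published MEWS variants;
the configurable YAML table (`load_table`) exists for auditing other cards.

Two rules need interpretation:

- **SpO₂.** The card awards 3 points for saturation below 90 % *despite
  adequate oxygen therapy*. Taken literally, desaturation on room air scores
  0, and that literal reading is implemented (the oxygen-therapy flag is
  carried on every SpO₂ recording).
- **Urine.** The card's rule is output below 75 ml over the previous 4 h
  (1 point); the threshold is configurable since local practice sometimes
  uses 24-hour production instead.

An assessment is **complete** iff all seven core elements (HR, SBP, RR,
temperature, SpO₂, AVPU, urine) are present. The worry flag is optional;
when absent it scores 0 rather than rendering the assessment incomplete.
Incomplete assessments are still scored over their present elements — the
total is then a lower bound — because downstream stratification by score
must handle the dominant case of real charts, where most assessments are
incomplete.

## Windowing

Recordings of one patient less than 15 minutes apart belong to one
assessment. The window is *anchored* at the first recording of a group, not
rolling: a rolling window would let measurements 14 minutes apart chain
without bound and would make the grouping order-dependent. Within a window a
repeated element supersedes its earlier value (a repeat within minutes is a
re-measurement); superseded rows stay attached to the assessment so the
grouping remains an exact partition of the input. Mixed-source groups take
the majority source, ties going to the automated device. No value is ever
carried forward across assessments and no imputation is performed.

## Adherence audit

The interval audited is anchor-to-anchor time to the next assessment of the
same stay, attributed to the stratum and the protocol window of the
*earlier* assessment (the protocol clock starts at the scored observation).
The terminal assessment of each stay has no successor; the default
denominator policy excludes it, and `terminal_nonadherent` is available to
approximate accounting schemes whose denominator is the total assessment
count. The audit can optionally be restricted to complete assessments;
by default partial scores are audited, since that is the only option that
covers real charts with few complete assessments.

## Statistics

Location comparisons use the Mann-Whitney rank-sum test: U from midranks;
for small tie-free samples (min(n) ≤ 8) a two-sided p from exact enumeration
of the null distribution of U (doubled folded lower tail, computed from the
Gaussian-binomial generating function); otherwise the normal approximation
with tie-corrected variance and a 0.5 continuity correction. 2×2 tables use
Pearson's chi-square without continuity correction unless any expected cell
is below 5, then Fisher's exact test (two-sided by tail summation of tables
at most as probable as the observed; tail doubling is available, as
different statistical packages disagree here). Interquartile ranges are
reported as a single width Q3 − Q1 under Tukey hinges (each half includes
the median for odd n); the quartile rule is configurable ("exclusive",
"linear") because published tables rarely state the rule behind their IQRs.
Percentages are printed to one decimal, rounded half-up. No multiplicity
correction is applied — none is appropriate for a descriptive operational
audit, and the tests mirror a two-sided α = 0.05 convention.

## Synthetic cohort generator

The generator exists to give every pipeline stage inputs with *known
truth*. Per patient: a stay of log-normal length (median 7.5 / 7.1 days and
IQR 7.0 / 6.0 days in the control / intervention arm); observation events
placed by a renewal process; at each event all eight elements drawn from
normal-physiology baselines (HR 80±10, SBP 125±15, RR 12±1.8, T 37±0.35,
SpO₂ 96.5±1.8, urine 200±60 ml/4 h); deterioration episodes arriving at
0.15/patient-day with log-normal duration (median 8 h) and severity
s ∈ [0.3, 1.2] that shifts values toward abnormal bands (HR +60·s,
SBP −45·s, RR +20·s, T +1.5·s, SpO₂ −8·s, urine ×(1−0.8·s), AVPU
+⌊2.5·s⌋), so all score strata from 0 to ≥4 occur.

Timing is **event-level**: the elements of one intended observation share an
event time with ≤5-minute offsets (minute resolution), and per-element
missingness then deletes elements — exactly the data structure the
missingness analysis measures. Default missingness is set from the reported
behaviour of the two recording regimes (respiratory rate 96 % vs 3 %
missing, consciousness 100 % vs 3 %; the remaining elements are set to
plausible intermediate values chosen once: temperature 35 %/15 %, urine
55 %/45 %, SpO₂ 25 %/3 %, HR and SBP 10 %/3 %). If every element of an event
is dropped, heart rate is kept so the event remains on the chart; under the
default configuration this affects well under 0.1 % of events.

Follow-up timing implements compliance as a per-event Bernoulli choice:
with probability c the next event is scheduled inside the protocol window
of the event's **observed** (post-missingness) score — preferring the next
nursing round (07:00/14:00/22:00 ± jitter) when it fits, which produces the
three daily peaks in the hourly pattern — and with probability 1 − c it
overshoots the window by a positive log-normal delay, snapped forward to
the round grid. Two details make the audited adherence recover c exactly:
scheduling against the observed score means the auditor (which can only see
recorded elements) reconstructs the same window; and each stay ends with
one terminal observation *at or after* the planned discharge rather than
truncating the walk when the next event would overshoot — truncation would
censor long (non-compliant) intervals preferentially and bias adherence
upward. An 8-minute margin between scheduled intervals and the window edge
absorbs within-event offsets and minute rounding; a 20-minute minimum gap
keeps intended events from merging in the 15-minute windowing.

Compliance defaults are per arm and recording source: 0.011 in the control
arm, 0.108 / 0.479 for conventional / automated events in the intervention
arm, whose events are automated with probability 0.39. Stay outcomes
(mortality, ICU readmission) and severity covariates (APACHE II/IV, SAPS II)
are drawn independently of the vitals process — the evaluation this package
supports found no outcome effect, and outcome fields exist only so report
tables have realistic content; coupling outcomes to deterioration is out of
scope. Randomness uses one named seed with per-patient substreams keyed by
(seed, arm, patient index), so cohorts of different sizes share their common
patients and a fixed configuration is byte-reproducible.

### What the generator does and does not emulate

It reproduces the *operational* statistical structure: per-element
missingness rates, the automated-use fraction, protocol-compliance rates,
round-clustered timing, and score strata with plausible occupancy. It makes
no claim to physiologic realism (no circadian or pharmacologic dynamics, no
correlation between elements beyond shared episodes), does not couple
outcomes to deterioration, and models compliance as memoryless. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims to measure on data of known structure — not that any particular
clinical result would replicate.

## Problem sizes

Recovery tests run at 300 patients/arm (≈3,000–4,000 assessments per arm,
a few seconds to generate), with tolerances of 3 binomial standard errors
at the realised assessment counts; shared fixtures elsewhere use 25
patients/arm. The exhaustive scoring check covers every integer heart-rate,
pressure and respiratory-rate value and the 0.1 °C temperature grid; the
rank-sum exactness check enumerates all rank assignments for every sample
split with n₁, n₂ ≤ 6.

## Known limitations

- The adherence audit covers only the monitoring-interval component of the
  response protocol; physician/RRT escalation actions leave no timestamp to
  audit.
- Completeness of an assessment says nothing about plausibility of its
  values; no physiologic cross-checks are performed.
- With heavy missingness the partial score underestimates the true score,
  so adherence measured against recorded scores is adherence to the score
  the staff could see, not to the unobservable true state — the same
  limitation the underlying charts have.
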