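# mewsaudit

Operational auditing of early-warning-score practice on a surgical
high-dependency unit (HDU), from raw time-stamped vital-sign recordings.

Track-and-trigger systems such as the Modified Early Warning Score (MEWS)
only work if nurses actually record the vital signs, compute the score, and
reassess within the interval the hospital protocol dictates. Evaluations of
such systems — in particular before/after comparisons of conventional
charting versus an automated bedside scoring device — therefore need to
answer *operational* questions from the chart itself: how many complete
score assessments were made, which elements went unrecorded, how long until
the next assessment after a given score, and how often the response protocol
was honoured. `mewsaudit` implements that entire audit as a reusable
pipeline, plus a synthetic two-arm cohort generator so every stage can be
exercised and validated without patient data.

## The score and the protocol

MEWS is a sum of per-element sub-scores. For a vital-sign vector
$x = (\mathrm{HR}, \mathrm{SBP}, \mathrm{RR}, T, \mathrm{SpO_2},
\mathrm{AVPU}, \mathrm{urine}, \mathrm{worried})$,

$$\mathrm{MEWS}(x) = \sum_j s_j(x_j), \qquad s_j(x_j) \in \{0,1,2,3\},$$

with band edges taken from the hospital's scoring card (heart rate 51–100
scores 0, >130 scores 3; systolic pressure <70 scores 3 but >200 only 2;
breathing faster than 30/min scores 3; fever never scores above 1;
AVPU A/V/P/U score 0/1/2/3; urine output <75 ml/4 h and nurse concern score
1 each; SpO₂ <90 % *despite oxygen therapy* scores 3). The maximum total is
19. The response protocol maps the current score to the maximum time until
the next assessment: 24 h at MEWS 0, then 8 h, 4 h, and 1 h at MEWS ≥ 3.

The pipeline stages, each its own module:

| stage | module | what it does |
|---|---|---|
| I/O | `records_io` | validated long-format CSV of recordings and stays |
| scoring | `scoring` | band tables, per-element sub-scores, MEWS totals |
| windowing | `assessments` | groups recordings <15 min apart into assessments |
| audit | `adherence` | time-to-next-assessment vs the protocol window |
| analytics | `analytics`, `stats` | missingness, hourly pattern, rank-sum and 2×2 tests, arm comparison |
| simulation | `simulate` | two-arm synthetic HDU cohort with known ground truth |
| CLI | `cli` | `mewsaudit simulate / audit / compare / report` |

## Worked example

```python
from mewsaudit import *

table = build_default_table()
obs = {
    ElementKind.HEART_RATE: (105, False),   # (value, on oxygen?)
    ElementKind.SYSTOLIC_BP: (95, False),
    ElementKind.RESP_RATE: (18, False),
    ElementKind.TEMPERATURE: (37.8, False),
    ElementKind.SPO2: (95, False),
    ElementKind.AVPU: (1, False),           # V — responds to voice
    ElementKind.URINE_4H: (60, False),
}
res = compute_mews(table, obs)
print("MEWS", res.total, "complete:", res.complete)
print("breakdown:", {e.value: s for e, s in res.breakdown.items() if s})
```

```
MEWS 6 complete: True
breakdown: {'HEART_RATE': 1, 'SYSTOLIC_BP': 1, 'RESP_RATE': 1, 'TEMPERATURE': 1, 'AVPU': 1, 'URINE_4H': 1}
```

Six elements sit one band away from normal, one point each; the nurse-worry
flag is absent and counts as "not worried", and all seven core elements are
present, so the assessment is complete. A MEWS of 6 requires reassessment
within the hour.

Running the full pipeline on a simulated two-arm cohort (50 patients/arm):

```python
cfg = paper_like_config(n_per_arm=50, seed=7)
stays, recordings, truth = generate_cohort(cfg)
ctl = build_assessments([r for r in recordings if r.period is Arm.CONTROL])
itv = build_assessments([r for r in recordings if r.period is Arm.INTERVENTION])
print(f"control: {len(ctl)} assessments, {completeness_counts(ctl)[1]} complete")
print(f"intervention: {len(itv)} assessments, {completeness_counts(itv)[1]} complete")
rc = adherence_rate(audit_assessments(ctl))
ri = adherence_rate(audit_assessments(itv))
print(f"protocol adherence: control {100*rc:.1f}%  intervention {100*ri:.1f}%")
```

```
control: 434 assessments, 0 complete
intervention: 621 assessments, 263 complete
protocol adherence: control 0.0%  intervention 27.1%
```

The conventional arm charts consciousness essentially never and respiratory
rate in ~4 % of observations, so no assessment is complete there, while the
intervention arm — a 39/61 mixture of automated and conventional recording —
reaches ~42 % completeness and far higher protocol adherence. The same
analysis is available from the shell:

```bash
mewsaudit simulate --out sim --seed 7 --n-per-arm 50
mewsaudit audit --recordings sim/recordings.csv --out audited
mewsaudit report --audit audited
```

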