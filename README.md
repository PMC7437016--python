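# petriage

Rule engines for pulmonary-embolism (PE) likelihood triage and a
diagnostic-accuracy framework for comparing them on AECOPD cohorts
(patients hospitalised with an acute exacerbation of COPD).

Patients with AECOPD have chronically elevated D-dimer, frequent
immobilisation, hypoxia and tachycardia, so PE rule-out strategies devised
for general emergency populations can behave pathologically in this group
— some image essentially everyone, others trade imaging burden for missed
diagnoses. `petriage` implements the five authoritative strategies as pure
decision functions over patient records and scores them against an
imaging reference standard, for clinical epidemiologists and decision-rule
researchers who want to audit or re-run such comparisons.

## The strategies

All share one Wells score (canonical weights 3, 3, 1.5, 1.5, 1.5, 1, 1)
and one clinical-pretest-probability (C-PTP) scheme per run. With strict
D-dimer comparisons (ng/ml), PE is ruled out by:

| strategy | rule-out condition |
|---|---|
| `standard` | low C-PTP and D-dimer < 500 |
| `age_adjusted` | low/moderate C-PTP and D-dimer < (500 if age ≤ 50 else age×10) |
| `years` | 0 of {DVT signs, hemoptysis, PE most likely} and < 1000; ≥ 1 and < 500 |
| `perc` | all eight: age < 50, SaO2 > 94 %, pulse < 100, no hemoptysis, no recent trauma/surgery, no VTE history, no unilateral leg swelling, no hormone use |
| `peged` | low C-PTP and < 1000, or moderate C-PTP and < 500 |

Anyone not ruled out requires chest imaging (CTPA and/or V/Q scan), which
is the *positive* prediction when scoring: the panel comprises
sensitivity, specificity, PPV, NPV, PLR = sens/(1−spec),
NLR = (1−sens)/spec, Youden index sens+spec−1 and diagnostic accuracy
(TP+TN)/N, plus imaging burden (TP+FP) and missed diagnoses (FN).

## Worked example

```python
from petriage import PETriageStudy

study = PETriageStudy.from_simulation(seed=42)   # synthetic AECOPD cohort
res = study.fit()                                # run all five engines + score
print(res.metrics["peged"].imaging_count, res.metrics["standard"].imaging_count)
print(res.metrics_frame()[["sensitivity", "specificity", "accuracy"]])
```

prints

```
925 1113
              sensitivity  specificity  accuracy
algorithm
standard            100.0          4.7      22.0
age_adjusted         99.5         20.6      34.9
years                99.0         22.6      36.4
perc                100.0          0.2      18.3
peged                99.0         24.4      37.9
```

On this synthetic cohort (n = 1158, 18.1 % PE prevalence) the graduated
strategy (`peged`) images 925 patients where the standard one images 1113
— the containment `imaging(peged) ⊆ imaging(standard)` is a theorem about
the rules, which the property tests verify. PERC clears almost nobody
(AECOPD patients are older, hypoxic and tachycardic, failing its criteria
wholesale), so its specificity collapses toward 0. Synthetic metric
*values* depend on the simulator's independence assumptions (see
`docs/methods.md`) — the qualitative ordering, not the digits, is the
reproducible part. A strategy that images literally everyone reports only
its PPV, with the rest of its row rendered N/A.

For real data, build the study from a CSV with a `confirmed_pe` column:

```python
res = PETriageStudy.from_csv("cohort.csv").fit()
print(res.summary())          # metric panel + pairwise grid, markdown
```

The same pipeline is scriptable from the shell:

```bash
petriage simulate --seed 42 --out cohort.csv
petriage triage --cohort cohort.csv --out decisions.csv
petriage evaluate --decisions decisions.csv --cohort cohort.csv \
    --fmt markdown --out report.md
petriage reproduce-tables     # recompute the published comparison tables
```

`petriage reproduce-tables` recomputes, from the packaged confusion-matrix
counts of a published three-hospital AECOPD comparison (n = 1158, 210
confirmed PE), the full eight-metric panel per strategy — e.g. the
graduated strategy's 88.6 / 80.7 / 50.4 / 97.0 % with PLR 4.591,
NLR 0.141, Youden 0.693, accuracy 82.1 % — and all ten pairwise
imaging/missed differences, and diffs every cell against the published
values (one known single-digit PLR truncation is documented in
`docs/methods.md`).

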