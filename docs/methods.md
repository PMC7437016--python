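# Methods

## Problem and scope

Acute pulmonary embolism (PE) is common and easily missed in patients
hospitalised for an acute exacerbation of COPD (AECOPD): baseline D-dimer
is elevated, immobilisation is frequent, and hypoxia and tachycardia are
near-universal, so rule-out strategies calibrated on general emergency
populations behave very differently here. `petriage` implements the five
widely used PE-likelihood strategies as deterministic rule engines over
patient records and the diagnostic-accuracy framework used to rank them
against an imaging reference standard, plus a synthetic AECOPD cohort
generator so the whole pipeline is testable without patient data.

Out of scope by design: EMR retrieval, imaging adjudication logic (the
reference standard enters as a single boolean per patient), the
echocardiography pathway for unstable patients, and downstream management
decisions. Verdicts are binary (rule out vs imaging required), as the
strategies themselves are; no probabilistic risk scores or ROC analysis.

## The rule engines

All engines share one Wells score and one C-PTP (clinical pretest
probability) scheme per run, mirroring a retrospective reassessment where
the stored Wells score and D-dimer feed every strategy. The Wells score is
the canonical seven-item weighted sum (3, 3, 1.5, 1.5, 1.5, 1, 1 points
for DVT signs, "PE most likely", HR > 100, immobilisation or surgery,
prior VTE, hemoptysis, cancer). Two three-level C-PTP presets ship:

* `peged-trial` (default): low ≤ 4.0, moderate 4.5–6.0, high ≥ 6.5 — the
  scheme under which the graduated-D-dimer strategy was defined;
* `traditional`: low < 2, moderate 2–6, high > 6.

Scores live on a half-point lattice, so the category boundaries are exact
comparisons with no floating-point tolerance. The choice of scheme is
genuinely open (source hospitals rarely document which variant they used);
it is configurable and echoed in every report header.

Decision clauses, with every D-dimer comparison strict ("less than"; ties
go to imaging):

| engine | rule-out condition |
|---|---|
| standard | low C-PTP and D-dimer < 500 ng/ml |
| age_adjusted | low/moderate C-PTP and D-dimer < (500 if age ≤ 50 else age×10) ng/ml |
| years | 0 of {DVT signs, hemoptysis, PE most likely} and < 1000; ≥ 1 item and < 500 |
| perc | all of: age < 50, SaO2 > 94 %, pulse < 100, no hemoptysis, no recent trauma or surgery, no VTE history, no unilateral leg swelling, no oral hormone use |
| peged | low C-PTP and < 1000, or moderate C-PTP and < 500; high always imaged |

Design choices where the published descriptions are ambiguous:

* The age-adjusted strategy's over-50 branch also requires low/moderate
  C-PTP (consistent with the strategy's source trial; its one-sentence
  summaries attach the C-PTP clause only to the ≤ 50 branch). Configurable
  via `age_adjusted_requires_cptp_over_50`.
* PERC's trauma/surgery criterion consumes `recent_trauma OR
  recent_surgery`; immobilisation alone does not fail PERC. Unilateral leg
  swelling is a distinct field from DVT signs (distinct clinical
  definitions); `perc_leg_swelling_from_dvt_signs=True` derives it if a
  data source only records the composite.
* PERC has exactly eight criteria; cancer is not one of them.

These decision functions obey two provable invariants, enforced by
property tests: the standard strategy's rule-out set is contained in both
the graduated and age-adjusted rule-out sets (under the shared scheme),
and every engine is monotone in D-dimer.

## Diagnostic-accuracy panel

The positive prediction is `imaging_required` (PE not excluded), so an
exhaustive strategy that images everyone has TP + FP = N and a false
negative is a missed diagnosis. The panel is sensitivity, specificity,
PPV, NPV, PLR = sens/(1−spec), NLR = (1−sens)/spec, Youden index
sens+spec−1, and diagnostic accuracy (TP+TN)/N.

Two rounding conventions:

* `published` (default): percentages half-up to one decimal; PLR, NLR and
  Youden computed from sensitivity/specificity first rounded to
  three-decimal proportions. This is how clinical DTA tables are
  conventionally assembled (ratios derived from the already-rounded
  percentages), and it reproduces the packaged reference panel digit for
  digit with one known exception — the age-adjusted PLR prints as 3.034 in
  the source table where both rounding paths give 3.035 (0.786/0.259 =
  3.0347, apparently truncated); the package reports 3.035 and records the
  discrepancy in the reproduction diff rather than adding a truncation
  mode.
* `exact`: unrounded proportions throughout; in this convention the
  identity ppv/(1−ppv) = PLR × prev/(1−prev) holds to 1e−9.

Undefined ratios (zero denominators) are reported as N/A, never thrown.
An engine with no rule-outs at all reports only PPV by default
(`exhaustive_na`), since sensitivity 100 %/specificity 0 % of an
exhaustive test carries no information; set `exhaustive_na=False` to get
the formal values.

Pairwise comparison reports imaging-count and missed-count differences as
absolute counts and percentages of the full cohort (half-up, one decimal);
the missed comparison is flagged N/A against an exhaustive strategy.

Group comparisons (PE-absent vs PE-present) use a two-sample t-test for
continuous variables (Student by default, `equal_var=False` for Welch) and
Pearson chi-square without continuity correction for booleans — the
combination that reproduces the reference cohort's printed p-values (e.g.
oral hormone use 0.021) from its 2×2 counts. No multiplicity adjustment is
applied, matching standard practice for baseline-characteristics tables.

## Synthetic cohort generator

Defaults emulate a 1158-patient AECOPD cohort with 210 imaging-confirmed
PE (18.1 % prevalence). Per truth group:

* **Allocation**: PE positives by exact count, round(n × prevalence), so
  the headline 948/210 split is reproducible, not a binomial draw.
* **D-dimer**: log-normal, moment-matched to mean ± SD (1191 ± 676 vs
  3118 ± 1635 ng/ml) — positive support and the right skew typical of
  D-dimer; only first and second moments are constrained.
* **Age**: truncated normal on [18, 100] at the group mean ± SD
  (66.9 ± 18.6 / 68.1 ± 20.3), as a two-component mixture pinning the
  under-50 fraction at 2.7 %/2.4 % (a plain truncated normal at those
  moments puts more mass under 50 than observed AECOPD cohorts).
* **Vitals**: heart rate and SaO2 are normals (SD 15 bpm and 3 %,
  plausible within-cohort spreads; not separately identified by the
  targets) whose means are solved so the exceedance fractions hit the
  targets — HR > 100 in 52.5 %/51.4 %, SaO2 ≤ 94 % in 85.0 %/89.5 % —
  with the threshold shifted half a unit because values are rounded to
  integers.
* **Booleans**: independent Bernoulli per group at the target prevalences
  (DVT signs 10.1 %/31.4 %, immobilisation 67.5 %/88.6 %, surgery
  10.4 %/21.4 %, VTE history 8.9 %/10.0 %, hemoptysis 7.0 %/5.7 %, cancer
  15.5 %/25.7 %, hormone use 29.0 %/37.1 %; trauma 5 % both groups — no
  published value), except two couplings: unilateral leg swelling is
  P = 0.60 given DVT signs else 0.05, and `pe_most_likely` is a logistic
  link on DVT signs (+1.0 log-odds) and immobilisation, surgery, VTE
  history and cancer (+0.5 each) with a per-group intercept solved by
  Brent's method so the expected fraction equals the target "PE likely"
  rate (58.5 %/84.3 %).

The Wells score is always computed from the generated items, never
sampled, so records are internally consistent; consequently the synthetic
Wells group means need not match any external mean ± SD, and
`validate_marginals` treats them as advisory (it does not check them).

What the generator does *not* model: the joint distribution (e.g.
D-dimer × Wells correlation within group), assay censoring, or site
effects — none of which the marginal targets constrain. Passing tests
therefore show that the engines and metrics behave correctly on a cohort
with realistic *marginals*, not that simulation reproduces any particular
study's confusion matrices; those are reproduced separately from the
packaged printed counts, and no attempt is made to tune the simulator
toward them.

`validate_marginals` checks each boolean/fraction target with an exact
two-sided binomial test (pass iff p ≥ alpha, default 0.001) and the
D-dimer mean and SD with z-intervals; the SD's standard error comes from
the moment-matched log-normal's fourth central moment (delta method),
because the normal-theory sd/√(2n) is far too tight for a heavy-tailed
law. `alpha` must lie strictly in (0, 1).

## Numerical conventions and degenerate inputs

* Rounding is decimal half-up (`Decimal`), not banker's rounding.
* Boolean CSV encodings accepted: 1/0, true/false, yes/no,
  case-insensitive; emitted as true/false. Round-trips are exact (floats
  written via `repr`).
* D-dimer is ng/ml throughout; `d_dimer_in_ug_ml=True` multiplies by 1000
  on ingest. No FEU/DDU conversion is attempted.
* Missing `confirmed_pe` is legal at read time (prospective use) and
  rejected at evaluation time, naming the first offending patient.
* Degenerate 2×2 tables in group comparison (item absent or universal in
  both groups) are flagged not-computable rather than raising.
* Problem sizes: the rule-oracle grid is 46,080 records, the nesting
  property runs on 10,000 random records, and parameter recovery uses 20
  cohorts of n = 1158 — sizes at which the binomial/z checks have sharp
  power while the full suite stays fast.

## Known limitations

* The simulator calibrates marginals only; simulated accuracy metrics
  depend on the assumed independence structure and should not be read as
  estimates for real AECOPD populations.
* The reference cohort's printed t-test p-values for age and BODE index
  are not reproducible from its printed summary statistics under either
  Student or Welch tests; the package computes t-tests honestly from data
  and makes no attempt to match those two cells.
* No confidence intervals on the accuracy metrics (binary verdicts, no
  resampling machinery); differences between strategies are reported as
  counts and percentages, without formal tests.
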