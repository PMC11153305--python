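# glycotrial

Outcome scoring and analysis for randomised trials of glucose-lowering
interventions in type 2 diabetes, built for the common primary-care setting
in which prescribers keep adjusting medication during follow-up, so the
glycaemic endpoint and the drug regimen confound each other.

The package is aimed at trial statisticians and methods researchers who need
the full chain — regimen scoring, composite endpoint classification,
contingency and mixed-model inference, stratified randomisation, and a
synthetic cohort generator that makes every stage testable without
participant-level data.

## The core quantities

**Medication effect score (MES).** For a drug prescribed at daily dose *d*
with maximum recommended monotherapy dose *D* and adjustment factor *f* (the
expected maximal HbA1c reduction, in percentage points, at dose *D*):

    MES = min(d / D, 1) x f

The total MES of a regimen is the sum over its drugs: the maximal HbA1c
reduction that regimen could be expected to deliver. A total MES of 2.5
reads as a maximal expected HbA1c decrease of 2.5 percentage points.
Adding the total MES to the measured HbA1c (%) gives **MES-corrected
HbA1c**, glycaemic control adjusted for the pharmacological support behind
it. Supra-maximal doses are capped at ratio 1 and flagged.

**Glycaemic management.** Each participant's change from baseline is
categorised twice — HbA1c (improved / stable / deteriorated at a symmetric
±5 mmol/mol ≈ 0.5 % threshold, boundaries inclusive) and medication
(decreased / stable / increased, escalation dominating) — and the two are
combined into a composite improved / stable / deteriorated category. Less
medication with a deteriorated HbA1c is classified deteriorated and flagged
for audit.

**Statistics.** Arm-by-category tables are tested with Pearson's
chi-squared; 2x2 tables get the Yates correction, and fall back to an exact
two-sided Fisher test (computed by exact integer enumeration) when any
expected cell count is below 5. Continuous outcomes use a linear mixed
model (time, time-by-arm, baseline value, sex, weight stratum; random
intercept per participant; REML), reporting the time-by-arm contrast with a
Wald 95% CI. Benjamini–Hochberg controls the FDR across secondary outcomes.
Intention-to-treat and per-protocol subsets are supported; no imputation.

## Worked example

`glycotrial.examples` ships the 12-month category counts of a published
two-arm trial of a monthly fasting-mimicking diet (FMD) added to usual care
(43 vs 39 classifiable participants, intention to treat). Encoding those
counts as a cohort and running the pipeline:

```python
from glycotrial import examples, run_pipeline
from glycotrial.simulate import cohort_from_counts

report = run_pipeline(cohort_from_counts(examples.ITT_12M), timepoint=12)
print(report.count_tables["glycaemic_management"])
for name, res in report.contingency.items():
    print(name, res.test_used, f"p={res.p_value:.4g}")
```

prints

```
         improved  stable  deteriorated
arm
FMD            23      10            10
control         3      13            23

medication_change chi_squared p=4.925e-05
hba1c_change chi_squared p=0.02337
glycaemic_management chi_squared p=3.118e-05
medication_stopped fisher_exact p=0.1598
additional_medication chi_squared_yates p=0.005616
```

Reading the output: glycaemic management improved in 53% of FMD vs 8% of
control participants and deteriorated in 23% vs 59% (chi-squared, df 2,
p < 0.001); the medication-change and HbA1c-change tables give p < 0.001 and
p = 0.02; stopping all medication (7 vs 2 participants) is tested by Fisher's
exact test because the smallest expected cell count is 4.3 (p = 0.16), while
additional-medication prescriptions (1 vs 10) pass the expected-count rule
and give a Yates-corrected p = 0.006.

A fully synthetic cohort goes through the same pipeline:

```python
from glycotrial import SimulationConfig, run_pipeline, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_participants=100), seed=3)
report = run_pipeline(cohort, timepoint=12, fit_effects=True)
```

or from the shell:

```
glycotrial simulate --seed 3 --out cohort.csv
glycotrial report --in cohort.csv --analysis-set itt --out report.json
```

## Layout

- `glycotrial.drugs` / `glycotrial.mes` — drug table, regimens, MES scoring
  (`MedicationEffectScorer` transformer)
- `glycotrial.classify` — category rules and `GlycaemicManagementClassifier`
- `glycotrial.ogtt` — Matsuda, insulinogenic and disposition indices
- `glycotrial.stats` — association tests, Fisher exact, BH, mixed models
  (`TreatmentEffectEstimator`), ITT/PP subsetting
- `glycotrial.randomize` — stratified permuted-block allocation
- `glycotrial.simulate` — synthetic cohort generator and count encoder
- `glycotrial.pipeline` / `glycotrial.cli` — cohort I/O, end-to-end reports

See `docs/methods.md` for the modelling assumptions and design choices.
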