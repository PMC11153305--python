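# Methods

This note records the models, conventions and design choices behind
`glycotrial`, in the order the pipeline applies them.

## Medication effect score

A prescription's score is `min(dose / max_dose, 1) x adjustment_factor`,
where the factor is the expected maximal HbA1c reduction (percentage
points) of the drug as monotherapy at its maximum recommended dose; a
regimen's total score is the sum over drugs, and an empty (diet-only)
regimen scores 0.

Choices worth stating:

- **Capping.** The score is a maximal *expected* reduction, so a dose above
  the monotherapy maximum cannot raise it further: the ratio is capped at 1
  and the drug flagged in `MesResult.capped_flags` rather than rejected.
- **Scale.** All MES arithmetic lives on the NGSP % scale; mmol/mol inputs
  are converted first with the NGSP master equation
  `% = 0.09148 x mmol/mol + 2.152` (exact linear inverse for the reverse
  direction). The packaged conversion reproduces standard paired table
  values (52.2 mmol/mol = 6.9%, 53.7 = 7.1%, ...) to one decimal.
- **Drug table.** Maximum doses and adjustment factors are clinical
  literature conventions, not constants of the method; they ship as
  `data/drug_table.json` (metformin, two sulfonylureas, a DPP4 inhibitor, a
  GLP-1 agonist, insulin) and are fully user-overridable. No factor is
  hard-coded in logic.

## Glycaemic-management classification

HbA1c change is categorised on the IFCC scale against a symmetric threshold
of 5 mmol/mol with **inclusive** boundaries (exactly −5 is improved,
exactly +5 deteriorated); percent-scale inputs are converted to mmol/mol
before thresholding, never the reverse, to avoid double rounding.
Medication change compares exact daily doses (doses are discrete tablet
multiples, so no tolerance band): any rise or added drug is an increase;
absent that, any fall or discontinuation is a decrease. Escalation
dominates mixed changes — any escalation signals failed glycaemic control.

The composite category is a total function over the 9 (medication, HbA1c)
combinations:

| medication \ HbA1c | improved | stable | deteriorated |
|---|---|---|---|
| decreased | improved | improved | **deteriorated** (flagged) |
| stable | improved | stable | deteriorated |
| increased | deteriorated | deteriorated | deteriorated |

The flagged cell — less medication but a deteriorated HbA1c — is the one
genuinely ambiguous combination; it is resolved as deteriorated and the
`tie_break_applied` flag is carried per participant so reports can count
how often the rule fired. The flag is arm-blind by construction.

Participants missing either visit's HbA1c are excluded from classification
and logged with a reason, mirroring loss to follow-up; counts are reported
against per-arm classified totals, with percentages always co-reported
alongside their counts (`round(100 x count / arm_total)`).

## OGTT indices

Curves carry samples at 0, 30, 60, 90, 120 min (missing post-load samples
tolerated down to two). Formulas operate in conventional units; SI inputs
are converted (glucose x 18.016 mmol/l→mg/dl; insulin ÷ 6.0 pmol/l→uU/ml —
the literature spans 6.0–6.945, so the constants used are recorded in
`units_note`).

- Matsuda index: `10000 / sqrt(G0 x I0 x Gmean x Imean)` with arithmetic
  means over all sampled values including t=0 (the original formulation; a
  trapezoidal-mean variant was considered and not adopted as default).
- Insulinogenic index: `(I30 − I0) / (G30 − G0)`; undefined when glucose is
  flat over the first half hour.
- Disposition index: Matsuda x a secretion measure. The secretion measure
  is configurable (insulinogenic by default, or the trapezoidal
  insulin/glucose AUC ratio over 0–120 min) because no single composition
  is canonical; no constant is tuned to reproduce any published
  disposition-index scale, and published OGTT-row means are treated as
  non-reproducible from summary data.

## Statistical layer

- **Association tests.** Pearson chi-squared with df = (r−1)(c−1);
  "assumptions violated" is operationalised as any expected cell count
  below 5. For 2x2 tables that rule triggers a two-sided Fisher exact
  test; otherwise 2x2 chi-squared carries the Yates continuity correction
  (the common package default). Degenerate tables (an all-zero row or
  column) are a hard error.
- **Fisher exact.** Implemented by exact integer combinatorics: the
  conditional distribution's unnormalised weights `C(r1,k) C(r2, c1−k)` are
  compared as integers, and the two-sided p-value sums all tables whose
  point probability does not exceed the observed one (point-probability
  ordering, the dominant convention). Because ties are integer
  comparisons, no floating-point tolerance enters; the implementation is
  tested exhaustively against an independent rational-arithmetic
  enumeration for every 2x2 table with N ≤ 40, and cross-checked against
  scipy.
- **Mixed models.** Follow-up visits (6, 12 months) are modelled with
  fixed effects for categorical time, time-by-arm, the baseline outcome
  value, sex and weight stratum, plus a per-participant random intercept,
  fit by REML (statsmodels MixedLM). The reported treatment effect is the
  time-by-arm contrast at the requested timepoint with a Wald 95% CI
  (profile CIs were not adopted). A post-hoc variant adds concurrent body
  weight as a fixed effect. Non-convergence raises with diagnostics.
- **Multiplicity.** Benjamini–Hochberg step-up over secondary-outcome
  p-values (statsmodels backend), adjusted values capped at 1.
- **Analysis sets.** ITT keeps every participant with baseline data;
  PP keeps intervention-arm participants compliant with the full programme
  who completed follow-up, plus control completers. Missing data are
  handled complete-case per timepoint; imputation is deliberately absent.

## Randomisation

1:1 stratified permuted blocks. Strata are sex x weight class; the weight
boundary is "above 100 kg", with exactly 100 kg assigned to the lower
stratum (a convention, stated rather than inferred). Block sizes are drawn
uniformly from {2, 4} per block (the mixing ratio is a free choice);
each block is a uniformly random permutation of a balanced arm sequence.
Consequences tested as properties: completed blocks are exactly balanced,
within-stratum imbalance never exceeds 2 at any enrolment prefix, and the
marginal allocation probability is 1/2. Plans record the seed and the
per-stratum block-size trace for audit.

## Synthetic cohort generator

The generator emulates a 100-participant, two-arm, 12-month trial with
visits at 0/6/12 months. Defaults (all overridable in
`SimulationConfig`):

- Baseline: HbA1c truncated-normal 52.2 ± 9.3 mmol/mol (floor
  20 mmol/mol); weight normal 100 ± 15 kg; age 62 ± 8 y; sex 50/50;
  fasting glucose 8.3 ± 1.9 mmol/l and insulin 156 ± 87.7 pmol/l drawn
  lognormal with those arithmetic moments (fasting analytes are
  right-skewed; a normal draw puts implausible mass near zero insulin);
  94% on metformin at doses on a 500-mg grid (median 1000 mg/day).
- Trajectories: follow-up = baseline + arm shift + shared participant
  intercept + visit noise. Default shifts (intervention relative to
  control): HbA1c −5.0 / −3.2 mmol/mol and weight −3.8 / −3.6 kg at 6 / 12
  months. Change-variance components (HbA1c intercept 4, residual
  3.5 mmol/mol; weight 2.5 / 1.5 kg) are sized so follow-up SDs stay near
  baseline SDs — HbA1c tracks strongly within person over 6–12 months and
  weight even more so. HbA1c change is additionally coupled to the
  within-arm residual of concurrent weight change (coefficient 0.5
  mmol/mol per kg); centring the coupling per arm keeps the configured
  shift equal to the true arm contrast, which the recovery tests rely on.
- Prescribing: a deliberate caricature of guideline-driven GP behaviour,
  applied at each follow-up visit with 80% adherence — above 53 mmol/mol,
  step metformin up 500 mg (to 3000 mg max, then add a second agent);
  below 48 mmol/mol with ≥3% weight loss, step down or stop. Its purpose
  is to make medication-change categories emerge endogenously, not to
  model care.
- OGTT: multiplicative post-load excursions peaking at 30–60 min; the
  insulin excursion scales with a lognormal per-participant
  insulin-resistance parameter times a global scale of 2.5, calibrated
  once so the simulated cohort-mean Matsuda index sits near 1.5 (SD ≈ 1.0),
  the insulin-resistant range typical of this population. The zero-
  resistance limit is a flat insulin curve.
- Dropout: missing-at-random per arm (defaults 16% intervention / 20%
  control), censoring from a uniformly chosen follow-up visit onward.
  Compliance with the intervention is Bernoulli (default 0.6).

Everything is deterministic given (config, seed); independent RNG streams
are spawned per stage so enabling one stage never perturbs another.

What the generator does **not** emulate: real within-participant
correlation structure and HbA1c–weight coupling (unpublished; defaults are
plausible, not validated), regression to the mean in follow-up values,
seasonal or assay drift, informative dropout, multi-drug baseline
regimens, and any physiology of the dietary intervention itself. Passing
tests therefore demonstrate correctness of the pipeline's logic and
estimators under a known data-generating process — not fidelity of the
generator to any real cohort.

## Problem sizes in the test suite

Desk-reproducible checks (encoded contingency tables, conversions, score
arithmetic) run at published trial size (n ≈ 82 classifiable). Law-of-
large-numbers checks of generator moments use n = 5000. Mixed-model
effect-recovery checks inject −3.2 mmol/mol (HbA1c), −0.3 (medication
score) and −3.6 kg (weight) at 12 months and require the estimate within
15% relative error at n = 2000 participants, averaging three independent
replicates so the check's own Monte-Carlo error (single-replicate SE
≈ 0.25 mmol/mol) stays small relative to the band. The type-I-error check
runs 2000 multinomial-null replicates and requires the rejection rate
within three binomial standard errors of 5%. The Fisher implementation is
swept exhaustively over all 135,751 tables with N ≤ 40.

## Known limitations

- Adjustment factors are literature conventions; analyses of real data
  should supply a curated drug table.
- The mixed model assumes a common residual variance across timepoints and
  arms and reports Wald intervals; small-sample df corrections are not
  applied.
- The per-protocol rule assumes a recorded boolean compliance flag; partial
  compliance is not graded.
- The generator's additive baseline-tracking trajectory model cannot
  produce follow-up SDs below the baseline SD (no regression to the mean).
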