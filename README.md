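# fasila

The FASILA bedside triage score for abdominopelvic trauma — FAST result,
shock index and serum lactate combined into a 0–6 score — together with the
full validation toolkit around it: comparator scores (ABC, systolic and
diastolic shock index), diagnostic-accuracy statistics, tie-aware
ROC/AUROC with bootstrap comparison, correlation and group-comparison
tests, IRLS logistic regression, a deterministic cohort fixture built from
per-score-level counts, and a seeded stochastic cohort simulator.

## Score definition

* FAST: negative = 0, positive = 1.
* Systolic shock index (HR/SBP): `< 0.70` → 0, `0.70–0.79` → 1,
  `0.80–0.89` → 2, `≥ 0.90` → 3.
* Lactate (mmol/L): `≤ 2.0` → 0, `2.0–4.0` (exclusive) → 1, `≥ 4.0` → 2.
* Total 0–6; risk class low `< 4` vs high `≥ 4` (cutoff configurable).

## CLI

```sh
# deterministic 400-patient fixture expanded from per-score-level counts
fasila simulate --fixture table1 -o cohort.csv

# seeded stochastic cohort
fasila simulate --n 1000 --seed 7 -o sim.csv

# append score columns (fast/si/lactate points, totals, risk class, ABC, SIs)
fasila score cohort.csv -o scored.csv

# evaluation report: group comparison, correlations, diagnostic panels,
# AUROC set, logistic regression, post-hoc power (JSON + text tables)
fasila evaluate scored.csv -o report/ --outcome surgery --seed 1

# score + evaluate in one step
fasila report cohort.csv -o report/
```

Exit codes: 0 success, 2 schema/config error, 3 statistical degeneracy
(e.g. a single-class outcome).

### Cohort CSV schema

One header row, columns named exactly as the patient-record fields, enums
lowercase, booleans `true`/`false`, optional fields (`pelvic_ais`,
`fibrinogen`) may be empty. Example row:

```csv
patient_id,age,sex,mechanism,hr,sbp,dbp,fast,lactate,gcs,iss,abdominal_ais,rts,triss,sofa,transfused,blood_units,mtp,laparotomy,management,icu_los,hospital_los,mortality,pelvic_ais,fibrinogen
p001,36.0,male,blunt,95.0,100.0,70.0,positive,4.5,15,34,4,6.1,0.7,3,true,12,true,true,surgical,6.0,18.0,false,,1.8
```

`fasila score` appends: `fast_points`, `si_points`, `lactate_points`,
`fasila_total`, `fasila_class`, `abc_total`, `abc_mtp_predicted`,
`systolic_si`, `diastolic_si`, plus a `score_flag` column for rows that
cannot be scored (they are flagged, never dropped).

## Layout

| module | contents |
| --- | --- |
| `fasila.scores` | patient record type, FASILA/ABC/shock-index formulas |
| `fasila.diagnostics` | confusion tables, CIs, ROC/AUROC, bootstrap, odds ratios, correlations, group tests, IRLS logistic regression, power |
| `fasila.cohort` | fixture specification + deterministic expansion, stochastic simulator |
| `fasila.io` | cohort CSV schema, parsing and validation |
| `fasila.report` | cohort scoring, report assembly, text rendering |
| `fasila.cli` | `fasila` command-line entry point |
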