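# comorbidx

Comparison of ICD-10 comorbidity measures as predictors of 12-month
functional recovery after orthopaedic injury.

## The problem

Risk adjustment for functional outcomes after injury needs a defensible
way to account for pre-existing conditions. Hospital-episode data carry
ICD-10-AM diagnosis codes (in Victorian data, prefixed `P` principal /
`A` additional / `C` in-hospital complication), from which several
competing comorbidity measures can be derived. `comorbidx` implements a
full pipeline for comparing four of them as adjustment terms in
logistic models of recovery:

- **CCI** — the 19-condition Charlson Comorbidity Index, with condition
  weights 1/2/3/6 summed to a score;
- **FCI** — the 18-condition Functional Comorbidity Index (unweighted
  count), developed with physical function as the outcome;
- **ICD-10 chapters** — indicators for chapters I–XVII and XIX, and the
  number of distinct chapters represented;
- **Haagsma six frequent chronic conditions** — chronic non-specific
  lung disease, heart disease, diabetes, backache, osteoarthritis,
  rheumatoid arthritis, with everything else as "other".

Before mapping, codes that are not comorbidities are removed: all
`C`-prefixed codes, `P`-prefixed Chapter XIX codes (the injury itself),
all of Chapter XVIII (symptoms and signs), Chapters XX–XXII, and an
editable blocklist of erroneously coded acute complications (acute
post-haemorrhagic anaemia, acute subendocardial MI, acute renal
failure, acute respiratory infections, fever, post-traumatic amnesia).

The outcome is the Glasgow Outcome Scale – Extended (GOS-E);
scores 7–8 are "recovered", <7 ongoing disability. For each measure,
models of the form

logit P(recovered) = β₀ + **injury** + **age** + **comorbidity**

are fitted by maximum likelihood on a random half of the cohort
("training") and applied to the held-out half ("test"), where
**injury** is the 10-level orthopaedic injury group plus four
non-orthopaedic injury flags, **age** is an 8-level categorical, and
**comorbidity** is either the 0/1/2+ category of a burden score or the
per-condition indicator variables (nine model variants in total).
Models are compared with likelihood-ratio tests, discrimination with
the DeLong AUC (95% CI) and paired DeLong chi-square tests, and
calibration with the Hosmer–Lemeshow statistic (10 risk-ordered bins,
df = 8) and calibration curves.

Because the source registry is not publicly deposited, the package
includes a synthetic registry generator whose defaults reproduce the
published cohort's marginal structure (age, mechanism and injury-group
distributions, condition prevalences, 42% recovered, ~12.6% loss to
follow-up skewed toward young male motor-vehicle cases).

## Worked example

```python
import comorbidx as cx

cfg = cx.SyntheticConfig(n=20_000, seed=7)
cohort = cx.generate_registry(cfg)
followed, lost = cx.apply_loss_to_followup(cohort, cfg)
report = cx.run_comparison(followed.patients, followed.diagnoses,
                           cx.RunConfig(seed=8))
print(report.training_table.to_string(index=False))
```

prints

```
             model   auc  auc_ci_low  auc_ci_high  hl_stat   hl_p  lr_stat     lr_p
            injury 0.593       0.581        0.605     0.95 0.9662      NaN      NaN
        injury_age 0.708       0.697        0.719    13.40 0.0989   924.91 0.000000
     chapter_count 0.722       0.711        0.733    13.19 0.1054   160.93 0.000000
chapter_indicators 0.721       0.711        0.732    14.66 0.0661   150.30 0.000000
     haagsma_count 0.710       0.700        0.721     8.21 0.4136    28.50 0.000001
haagsma_indicators 0.721       0.711        0.732     4.77 0.7820   161.48 0.000000
      cci_category 0.714       0.703        0.725     7.92 0.4408    73.51 0.000000
      fci_category 0.714       0.703        0.724     5.12 0.7452    65.29 0.000000
    fci_indicators 0.715       0.704        0.726     5.78 0.6714      NaN      NaN
```

Reading the table: injuries alone discriminate recovery poorly
(AUC 0.59); adding age lifts the AUC to 0.71 (LR χ² = 924.9 against the
injury-only model); every comorbidity term adds a further significant
improvement (LR tests against the injury+age model), with AUCs of
0.71–0.72 and little separating the four measures — chapter-based
adjustment edges out the others. Non-significant H-L p-values mean no
detectable miscalibration in-sample. `report.test_table` holds the
held-out metrics (training coefficients applied to the test half) and
`report.auc_comparisons` the paired DeLong tests, e.g. chapter count vs
six-condition count: χ²₁ = 36.99, p < 0.001 on this cohort.

The same pipeline runs from the shell:

```bash
comorbidx generate --n 20000 --seed 7 --with-loss --out cohort/
comorbidx map --patients cohort/followed/patients.csv \
              --diagnoses cohort/followed/diagnoses.csv --out profiles.csv
comorbidx run --patients cohort/followed/patients.csv \
              --diagnoses cohort/followed/diagnoses.csv --seed 8 --out results/
```

Real data can be supplied in the same two CSVs: a patients table
(`patient_id, age_group, gender, mechanism, injury_group, head_injury,
rib_fractures, organ_injury, burns, gose`) and a long diagnoses table
(`patient_id, seq, prefix, icd10_code`, dotted or dotless codes).

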