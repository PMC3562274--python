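# Methods

## Scope and data model

`comorbidx` compares four ICD-10-based comorbidity measures as
risk-adjustment terms in logistic models of 12-month functional
recovery after orthopaedic injury. A cohort is two tables: a patients
table (age group, gender, injury mechanism, 10-level orthopaedic
injury group, four non-orthopaedic injury indicator flags, GOS-E) and
a long diagnoses table of prefixed ICD-10-AM codes (`P` principal, `A`
additional, `C` in-hospital complication; up to 40 per admission).
Codes are stored dotless and uppercase (letter + 2–4 digits).

## Comorbidity selection

A code counts as a comorbidity only if it survives, in order: (i) drop
all `C`-prefixed codes; (ii) drop `P`-prefixed Chapter XIX codes (the
injury principal diagnosis — `A`-prefixed Chapter XIX codes such as
old-injury T90–T98 survive); (iii) drop all Chapter XVIII codes
(symptoms and signs); (iv) drop Chapters XX–XXII; (v) drop codes on a
blocklist of erroneously coded acute complications; then deduplicate.
Chapter membership uses the WHO chapter bands (I: A00–B99 … XXII:
U00–U99), shipped as package data; codes in unused gaps between bands
(e.g. D49) are rejected as invalid.

The blocklist is shipped as an editable CSV
(`comorbidx/data/blocklist.csv`). The named conditions are standard;
their code spans (D62, I21.4, N17, J00–J22, R50, R41.1) are this
package's interpretation, since only condition names are conventional.
The R-spans are redundant with rule (iii) but kept for auditability.

## Range matching

Mapping tables print ranges at mixed granularity. A range printed at
3 characters (`I21-I24`) contains any code whose 3-character
truncation lies in the band; a 4-character range (`M05.0-M05.9`)
matches on the 4-character truncation, and a shorter code matches iff
some digit-extension of it would. One exception: where a table lists a
bare 3-character code in a row whose 4th-character subdivisions belong
to a *different* condition (the Charlson diabetes row lists E10/E11/
E13/E14 next to subdivisions that the end-organ-damage condition
claims), the bare code is stored with an `exact` flag and matches only
literally. Without this, a truncation match would merge the two
diabetes severities the index deliberately separates.

## The four measures

All measures are presence-based on the deduplicated post-selection
code set; one code may flag several conditions (M48.0 is
simultaneously FCI arthritis, Haagsma osteoarthritis and Haagsma
backache), and no deduplication occurs across conditions.

- **CCI**: 19 conditions with weights following Charlson's
  recommendation (1 for MI, CHF, PVD, dementia, cerebrovascular,
  chronic pulmonary, connective tissue, ulcer, mild liver, diabetes;
  2 for hemiplegia, renal, diabetes with end-organ damage, any tumour,
  leukaemia, lymphoma; 3 for moderate/severe liver; 6 for metastatic
  solid tumour and AIDS). The weight table is package data and
  editable. The dementia row includes F10 as printed in the source
  map, which makes alcohol-related disorders the dominant contributor
  to that condition; implemented as printed.
- **FCI**: 18 unweighted conditions; score 0–18.
- **Chapters**: indicators over I–XVII and XIX; the count is the
  number of distinct chapters represented.
- **Haagsma**: six specific conditions plus an "other" indicator. By
  default the burden count covers the six specific conditions only;
  `haagsma_count_includes_other=True` switches to including "other"
  (the published tables are ambiguous on this point).

Each burden score is categorised 0 / 1 / 2+ for use as a model
covariate, since condition counts are not linearly related to the log
odds of recovery.

## Outcome and models

GOS-E 7–8 is "recovered", <7 ongoing disability; GOS-E 1 (death)
cannot occur in a survivors-to-discharge cohort and is rejected.
Records without a GOS-E are excluded listwise before splitting.

Nine model variants are fitted: injury block only (10-level injury
group + four non-orthopaedic flags); injury + 8-level age group; and
injury + age + one of seven comorbidity terms (0/1/2+ categories of
the chapter count, Haagsma count, CCI weight and FCI score; and the
chapter, Haagsma and FCI indicator sets). Categorical blocks are
dummy-coded against the most frequent level (recorded in the output);
burden categories use "0" as reference. Fits are maximum likelihood
(Newton–Raphson, relative log-likelihood tolerance 1e-8, max 100
iterations) via statsmodels behind the package's interface.

Degenerate designs are handled explicitly: single-class outcomes and
(quasi-)complete separation raise errors naming the offending column;
rank-deficient designs raise. At the estimator level
(`RecoveryModel.fit`), an indicator or dummy column that is constant
in the fitting half, or whose carriers all share one outcome, is
omitted and recorded in `dropped_` — at realistic prevalences some
cells are genuinely this sparse (a chapter with one case in 13,519),
and reporting a divergent coefficient would be worse than omitting
the term, which is also what standard fitting software does.

Likelihood-ratio tests compare injury+age against injury, and each
comorbidity variant against injury+age (chi-square, df = added
columns). The FCI-indicator variant is reported without an LR entry,
mirroring the reporting layout this package reproduces.

## Evaluation

- **AUC**: Mann–Whitney statistic with ties counted ½; variance by
  DeLong structural components; 95% CI by normal approximation,
  truncated to [0, 1] (no logit transform).
- **Paired AUC comparison**: (AUC_a − AUC_b)² / Var(AUC_a − AUC_b)
  with the covariance from shared structural components; chi-square
  with 1 df. Identical predictions give statistic 0, p = 1.
- **Hosmer–Lemeshow**: records ranked by prediction and cut at
  quantiles into 10 groups by default; tied predictions always share a
  bin, so bins can merge and be unequal — this keeps the statistic
  independent of input order. df = realised bins − 2 in both the
  training and test halves (the external-validation df = g convention
  is not adopted; the choice is recorded in the report metadata). The
  g − 2 reference is exact only for in-sample fitted predictions;
  applied to true or externally transported probabilities the
  statistic is closer to chi-square(g), so test-half p-values are
  mildly anti-conservative — a property shared by the reporting
  convention this package follows.
- **Calibration curves**: per-quantile-bin mean prediction vs observed
  event proportion, exported for plotting.

The test half is scored with the training coefficients (no refitting);
`refit_on_test=True` switches to refitting, since the convention is
ambiguous in this literature.

## Synthetic registry generator

The source registry is not deposited, so the generator emulates its
statistical structure; defaults are the study conditions.

- Marginals: age (8 groups), gender (54.5% male), mechanism (8
  levels) and injury group (10 levels) drawn independently from the
  published followed-up cohort distributions.
- Comorbidity: ~46 conditions sampled as marginally independent
  Bernoulli draws with prevalences mirroring the published condition
  table; for a sampled condition one code is drawn uniformly from that
  condition's pool and attached with prefix `A`. Pools are pairwise
  disjoint so configured marginal prevalences remain identifiable
  after mapping. Age multipliers (0.3 → 2.0 from youngest to oldest,
  normalised so the marginal prevalence is preserved) make older
  patients carry more comorbidity.
- Injuries: each injury group attaches 1–3 `P`-prefixed Chapter XIX
  codes; the non-orthopaedic flags attach `P`-prefixed concurrent
  injury codes; 5% of records get a `C`-prefixed complication noise
  code; 2% get an `A`-prefixed blocklisted acute-complication code
  (all filtered upstream of the measures by construction).
- Outcome: logit P(recovered) = intercept + age effects (0 to −1.9
  with age) + injury-group effects (−0.8 to +0.6) + flag effects
  (−0.3 to −0.7) + chapter-burden category effects (−0.45 for one
  chapter, −0.9 for 2+). The intercept is calibrated by root-finding
  so the expected recovered fraction equals the 0.42 target on the
  generated cohort. Recovered GOS-E is uniform on {7, 8},
  non-recovered uniform on {2..6} (only the dichotomy is analysed).
- Loss to follow-up: per-record probability = age-group base (0.177
  young → 0.067 oldest) × gender multiplier (1.12 male / 0.86 female)
  × mechanism multiplier (1.30 motor vehicle / 0.95 otherwise),
  giving ~12.6% overall loss skewed toward young male motor-vehicle
  cases; lost records have GOS-E removed.

What the generator does **not** emulate: the joint dependence between
conditions. Real comorbidities cluster far more than independence
implies — indeed the published marginal prevalences (summing to ~0.69
across chapters) are arithmetically incompatible with the published
chapter-count distribution (26% zero, 52% with ≥2) under *any* joint
distribution, so both cannot be matched; the generator follows the
marginal prevalences and consequently produces more zero-burden
patients (~52%) than the printed count distribution. It also ignores
hospital-level clustering and any injury–comorbidity dependence.
Passing tests therefore demonstrate correctness of the mapping,
modelling and evaluation machinery under a plausible cohort, not
fidelity to the source registry's joint distribution.

Because loss to follow-up removes younger (higher-recovery) patients,
the followed-up subset's recovered fraction sits slightly below the
generated cohort's 42% target (typically 40–42%).

## Numerical conventions and problem sizes

Split halves are exact: floor(n/2) and the remainder, by seeded
permutation. One seed drives generation, loss, splitting and the
report. Percentages are reported to one decimal. The test suite
exercises the pipeline at n = 4,000–20,000 and Monte-Carlo checks at
n = 50,000–100,000; `scripts/acceptance.py` uses the study scale
(15,471 survivors, ~13,500 followed up). Type-I-error suites use
1,000 small-sample replicates; parameter recovery uses 200 cohorts of
n = 20,000.

## Known limitations

- The 10 orthopaedic injury groups are taken as an input field; no
  ICD-10 → injury-group mapping is provided.
- No ICD-9 or ICD-10-CM dialect support beyond dotted/dotless
  normalisation; no Elixhauser or other indices; no severity weighting
  outside the CCI; no multiple imputation (complete-case by design).
- Model coefficients depend on reference-level choices and are not
  comparable across software without aligning references; only
  model-level statistics (AUC, H-L, LR) are.
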