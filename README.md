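# gpospom

Table-driven calculation and external validation of POSPOM-style
preoperative mortality scores on ICD-10/OPS-coded hospital case registries.

## The problem

The Preoperative Score to Predict Postoperative Mortality (POSPOM,
Le Manach et al. 2016) estimates a surgical patient's risk of in-hospital
death from preoperatively available administrative data alone. It is an
additive integer score

```
POSPOM = age points + Σ comorbidity points + surgery-category points
```

where the age contribution comes from the patient's age band, each of 15
comorbidity groups (defined by ICD-10 code prefixes) contributes its points
at most once, and the index surgery (defined by procedure-code prefixes —
OPS in German §21 KHEntgG billing extracts) contributes the points of its
category. Validating such a score on a hospital's own registry requires a
reproducible pipeline: code normalization, an eligibility cascade with full
attrition accounting, per-case score decomposition, and the standard
external-validation battery — c-statistic (area under the ROC curve), Brier
score, calibration plot, per-score observed mortality, and Wald confidence
intervals for the mortality proportion.

`gpospom` implements that pipeline for epidemiologists and perioperative
researchers working with German-style case-level billing extracts. The
point table is **configuration, not code**: the package ships a JSON Schema,
a transcription template with the canonical group names
(`gpospom/data/point_table_template.yaml`), and a clearly labelled
*synthetic* demo table so every stage runs out of the box. Because real
§21 extracts cannot be shared, a synthetic-registry generator with a known
data-generating process (truncated-normal score distribution, logistic
score→mortality link) is a first-class component: it is what lets the
validation battery itself be validated.

## Worked example

```bash
# 1. simulate a 50,000-case registry from the demo table and demo link
gpospom simulate --mode cohort --n 50000 --seed 1234 --out registry.csv

# 2. score it and run the full validation battery
gpospom validate --registry registry.csv --out-dir results/
```

The second command logs (stderr, INFO):

```
INFO gpospom.cohort_filter: eligibility: 50000 input, 0 without index procedure,
    0 under 18, 0 incomplete, 50000 included
INFO gpospom: n=50000 deaths=917 mortality=1.83% (95% CI 1.72-1.95)
INFO gpospom: mean score 18.44 (SD 7.79), median 18.0, max 49
INFO gpospom: c-statistic 0.790
INFO gpospom: Brier score 0.0173
```

and writes `results/validation_report.json` (cohort summary, attrition,
point decomposition, AUC, Brier, calibration fit, per-score mortality) plus
ROC, calibration and score-distribution figures as SVG and PNG. Reading the
numbers: 917 of 50,000 simulated cases died in hospital (1.83%, Wald 95% CI
1.72–1.95%); the score discriminates deaths from survivors with c = 0.791
(the probability a random death out-scores a random survivor); the Brier
score 0.0173 is the mean squared gap between the logistic link's predicted
probabilities and the 0/1 outcomes. (c = 0.790 here is a property of the
simulated case mix, not a quality benchmark: with a steeper or shallower
score distribution the same perfectly specified link yields a different
AUC.) Because this cohort was simulated from that very link, the
calibration fit hugs the identity line — on real data the same plot is the
honest check of transportability.

For a real analysis, replace the demo table by your transcription of the
published point values (start from
`python -c "import gpospom; print(gpospom.point_table_template_path())"`)
and point `--registry` at your extract
(`case_id,age,sex,icd_codes,ops_codes,ops_dates,admission_date,discharge_date,discharge_reason`,
code lists `|`-separated, dates ISO-8601).

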