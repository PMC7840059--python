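# Methods

## The score model

A POSPOM-style score is a deterministic integer function of a hospital
case's administrative record:

```
score = age_points(age) + Σ_g 1[any ICD code matches g] · points_g + points_surgery(case)
```

* **Age**: one contribution from the unique age band containing the integer
  age. Bands are inclusive on both ends, must not overlap, and must jointly
  cover every adult age (the top band is open-ended). The table validator
  enforces this, so band lookup is total on eligible cases.
* **Comorbidities**: each group is a set of normalized ICD-10 prefixes with
  an integer point value. A code matches a prefix iff the normalized code
  starts with the prefix — the semantics of every ICD/OPS grouper table,
  mirroring the classification's hierarchy. A group scores at most once per
  case, so duplicated or sibling codes (I50.1 and I50.9) cannot inflate the
  score; groups may overlap (a code can fire several groups) because the
  published score defines them independently. Normalization is uppercase +
  dot/whitespace stripping ("I50.1" → "I501"), applied identically to table
  prefixes and record codes, and idempotent.
* **Index surgery**: among procedures matching any surgery-group prefix,
  the chronologically first is assigned; among procedures tied on the
  earliest date — and when no dates are recorded at all, which is treated
  as "all simultaneous" — the matching group with the most points wins.
  A residual tie (same date, same points, different groups) breaks
  lexicographically by group name: the published rule is silent there and
  determinism matters more than any particular choice. Surgery prefixes are
  validated for ambiguity (no two groups may be able to claim the identical
  full code); comorbidity prefixes are not, by design.

The point values themselves are user configuration (YAML/JSON against a
shipped JSON Schema). The packaged `synthetic_demo_table.yaml` has the
published table's *shape* — six age bands, 15 comorbidity groups, a maximum
attainable score of 49 — but synthetic point values, and says so in its
version string; transcription of the published values into
`point_table_template.yaml` is deliberately left as the user's auditable
step rather than hard-coded, because a silent transcription error shipped
as package ground truth would be worse than none.

## Eligibility cascade

Exclusions are applied sequentially — (1) no index procedure, (2) age under
18, (3) incomplete record — and each case is counted in exactly one bucket,
so the attrition report partitions the input and its counts always
reconcile (enforced as a dataclass invariant). Order matters and is fixed:
a 15-year-old with no index procedure counts as "no index procedure". A
case with *missing* age is not assertable as under-age and falls through to
"incomplete". An empty diagnosis list is complete: absence of coded
comorbidity is informative (zero comorbidity points), not missing data.

Death is derived from the discharge-reason code; the default death-code set
`{"07"}` follows §21 KHEntgG discharge-disposition conventions and is
configurable.

## Validation battery

* **c-statistic**: computed by the Mann–Whitney rank-sum formula with
  mid-ranks, which equals the pairwise definition (concordant + ½·tied) /
  (deaths × survivors) exactly, and equals the trapezoidal area under the
  ROC curve built by thresholding at every distinct score. The suite checks
  all three routes against each other and against an independent
  implementation.
* **Brier score**: mean squared difference between predicted probability
  and outcome. Predictions come from a configured risk map — either a
  per-score probability table (validated to cover every attainable score)
  or a logistic curve in the score.
* **Mortality CI**: Wald normal approximation `p ± z√(p(1−p)/n)`, reported
  in percent, rounded half-up to two decimals, clipped to [0, 100]. At the
  cohort sizes this pipeline targets (n ≈ 2·10⁵, p ≈ 2%) Wald, Wilson and
  Clopper–Pearson agree to the printed precision; Wald is used because it
  is the convention the reported intervals in this literature reproduce.
* **Calibration**: one point per integer score value — (predicted risk,
  observed mortality) — summarized by a least-squares line; slope 1 and
  intercept 0 is perfect calibration. The **default fit is unweighted**
  over those dots, exactly what a calibration figure shows. Two weighted
  variants exist: `cases` (weight = cell size) and `inverse_variance`
  (weight = nₛ/(pₛ(1−pₛ)), the efficient WLS weighting when cell outcomes
  are binomial). The distinction matters: in a cohort of 50,000 the extreme
  score cells hold a handful of cases, their observed mortality is nearly
  pure noise, and they are the high-leverage points of an unweighted fit —
  its slope estimate has a standard deviation of roughly 0.2 under the
  simulator's own data-generating process, versus ≈ 0.03 for the
  inverse-variance fit. Recovery tests of the generating link therefore use
  `inverse_variance`; figures use the unweighted line.
* **Summaries**: sample SD (n−1 denominator, the epidemiological
  convention), midpoint median for even n, percentages rounded half-up to
  2 decimals at report time with full precision kept in the JSON report.
  Per-sex strata are recomputed from the cases; if a summary is constructed
  from externally supplied aggregates whose strata do not sum to the total,
  the discrepancy is surfaced as `stratum_sum_delta`, never reconciled
  silently.

## Synthetic registry generator

The generator emulates the *statistical structure the analysis assumes*,
not any real case mix:

* **Scores first, codes second.** Integer scores are drawn from a normal
  distribution truncated to the table's attainable range and rounded to the
  nearest attainable score (ties upward — attainable sets can have gaps
  under small tables). Codes are then *inverse-constructed*: an age band,
  surgery group and comorbidity subset whose points sum exactly to the
  drawn score, chosen uniformly at random among valid decompositions via a
  subset-sum reachability table. Every generated case round-trips through
  the scoring engine to exactly its intended score, which is what gives the
  validation battery a known ground truth.
* **Defaults.** Score mean 18.18 and SD 8.11 points, female share 49.24% —
  the headline values of a large (≈ 2·10⁵ cases) German university-hospital
  surgical cohort. Note the *realized* mean of the truncated discretized
  distribution is ≈ 18.44, not 18.18: truncation at zero is asymmetric.
  `score_distribution()` returns the exact discrete law, and recovery tests
  compare against its analytic moments, not the nominal inputs.
* **Outcome link.** Logistic, intercept −7.2 and slope 0.143 per point,
  anchored by hand to published per-score observed mortality in the same
  cohort (≈ 0.3% at 10 points, ≈ 18% at 40). This yields an overall
  simulated mortality near 2%, in the right clinical range.
* **Attrition fixture.** Exact stratum counts (default 357,861 total;
  115,281 without index procedure; 41,836 minors; 964 incomplete; 4,053
  deaths among the 199,780 eligible), shuffled, deterministic per seed.
  Ages are uniform within the decomposition's age band; sex is independent
  of score.

**What passing tests do and do not show.** The simulator has no ICD
frequency spectrum, no correlation between comorbidities, age, sex and
surgery type, no seasonal or secular trends, no coding errors, and a
symmetric unimodal score distribution where real cohorts are right-skewed.
Green recovery tests demonstrate that the pipeline's arithmetic and
statistics are correct under a known data-generating process — they say
nothing about how well any particular point table predicts mortality in
real patients, which is precisely the question an external validation on
real data answers.

## Numerical choices and degenerate inputs

* Inverse-logit is evaluated in its numerically stable branch form.
* Half-up rounding goes through `Decimal(str(x))` so the value rounded is
  the shortest decimal representation, not the binary expansion.
* Single-class cohorts (no deaths or no survivors): the c-statistic is
  undefined; the report carries `auc: null` rather than failing.
* Calibration with fewer than two distinct predicted values, summaries of
  empty cohorts, and CI at n = 0 raise `UndefinedStatisticError`.
* An all-zero point cohort defines all decomposition shares as 0.
* Unattainable simulation targets raise an error listing the nearest
  attainable scores.

## Problem sizes

The shipped tests exercise the full-scale attrition fixture (357,861
cases), a 50,000-case recovery cohort, 10,000 inverse-construction round
trips and 200 randomized oracle cohorts; the whole suite runs in well under
a minute on a single core, so these sizes are comfortable defaults rather
than upper limits.

## Known limitations

* Unit of analysis is the hospital case; repeated stays by one patient are
  independent rows (no patient-level clustering or linkage).
* No DeLong CI for the AUC, no Hosmer–Lemeshow test, no recalibration or
  refitting of the score.
* No automated translation between procedure classifications (CCAM/GHM →
  OPS); only the prefix-table schema for the result of such a mapping.
* Wald intervals undercover for very small n or k near 0 — acceptable at
  registry scale, not for small subgroups.
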