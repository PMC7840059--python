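{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/gpospom/validation_report.schema.json",
  "title": "Validation report",
  "type": "object",
  "required": ["summary", "attrition", "point_decomposition", "auc", "brier",
               "calibration", "per_score_mortality"],
  "properties": {
    "summary": {
      "type": "object",
      "required": ["n_cases", "n_deaths", "mortality_pct", "mortality_ci_pct",
                   "mean_score", "sd_score", "median_score", "mean_age",
                   "sd_age", "median_age", "max_score", "strata",
                   "stratum_sum_delta"],
      "properties": {
        "n_cases": {"type": "integer", "minimum": 0},
        "n_deaths": {"type": "integer", "minimum": 0},
        "mortality_pct": {"type": "number"},
        "mortality_ci_pct": {
          "type": "array", "minItems": 2, "maxItems": 2,
          "items": {"type": "number", "minimum": 0, "maximum": 100}
        },
        "mean_score": {"type": "number"},
        "sd_score": {"type": "number"},
        "median_score": {"type": "number"},
        "mean_age": {"type": "number"},
        "sd_age": {"type": "number"},
        "median_age": {"type": "number"},
        "max_score": {"type": "integer"},
        "strata": {"type": "object"},
        "stratum_sum_delta": {"type": "integer"}
      }
    },
    "attrition": {
      "type": ["object", "null"],
      "required": ["n_input", "n_no_index_procedure", "n_under_18",
                   "n_incomplete", "n_included"]
    },
    "point_decomposition": {
      "type": "object",
      "required": ["total_points", "comorbidity_points_total",
                   "age_points_total", "surgery_points_total",
                   "comorbidity_share_pct", "age_share_pct",
                   "surgery_share_pct"]
    },
    "auc": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
    "brier": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
    "calibration": {
      "type": ["object", "null"],
      "required": ["slope", "intercept", "weighting", "points"]
    },
    "per_score_mortality": {"type": "object"}
  }
}
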