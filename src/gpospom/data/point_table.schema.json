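{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/gpospom/point_table.schema.json",
  "title": "POSPOM-style point table",
  "type": "object",
  "required": ["version", "age_bands", "comorbidities", "surgeries"],
  "properties": {
    "version": {"type": "string"},
    "age_bands": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["lower_age", "points"],
        "properties": {
          "lower_age": {"type": "integer", "minimum": 0},
          "upper_age": {"type": ["integer", "null"], "minimum": 0},
          "points": {"type": "integer", "minimum": 0}
        },
        "additionalProperties": false
      }
    },
    "comorbidities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "icd_prefixes", "points"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "icd_prefixes": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "pattern": "^[A-Z][0-9A-Z]*$"}
          },
          "points": {"type": "integer", "minimum": 0}
        },
        "additionalProperties": false
      }
    },
    "surgeries": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "ops_prefixes", "points"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "ops_prefixes": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "pattern": "^[0-9][-0-9A-Z]*$"}
          },
          "points": {"type": "integer", "minimum": 0}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
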