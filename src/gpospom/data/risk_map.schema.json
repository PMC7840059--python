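{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/gpospom/risk_map.schema.json",
  "title": "Score-to-probability risk map",
  "type": "object",
  "required": ["mode"],
  "properties": {
    "mode": {"enum": ["table", "logistic"]},
    "table": {
      "type": "object",
      "patternProperties": {
        "^[0-9]+$": {"type": "number", "minimum": 0, "maximum": 1}
      },
      "additionalProperties": false
    },
    "logistic": {
      "type": "object",
      "required": ["intercept", "slope"],
      "properties": {
        "intercept": {"type": "number"},
        "slope": {"type": "number"}
      },
      "additionalProperties": false
    }
  },
  "allOf": [
    {
      "if": {"properties": {"mode": {"const": "table"}}},
      "then": {"required": ["table"]}
    },
    {
      "if": {"properties": {"mode": {"const": "logistic"}}},
      "then": {"required": ["logistic"]}
    }
  ],
  "additionalProperties": false
}
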