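{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Cross-ome screen document",
  "description": "Export bundle of one pairwise regression screen: run configuration, threshold-filtered top table with per-row metrics and fitted-line geometry, and per-row sample-level data.",
  "type": "object",
  "required": ["config", "topTable", "data"],
  "additionalProperties": false,
  "properties": {
    "config": {
      "type": "object",
      "required": ["referenceCohort", "thresholdType", "thresholdValue", "m", "seed"],
      "additionalProperties": false,
      "properties": {
        "referenceCohort": {"type": "string"},
        "thresholdType": {"type": "string", "enum": ["raw_p", "fdr_p"]},
        "thresholdValue": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "minNonzero": {"type": "integer", "minimum": 0},
        "immuneTransform": {"type": "string", "enum": ["none", "sqrt"]},
        "metricColumns": {"type": "array", "items": {"type": "string"}},
        "cohortColors": {"type": "object", "patternProperties": {".*": {"type": "string"}}},
        "m": {"type": "integer", "minimum": 0},
        "seed": {"type": "integer"}
      }
    },
    "topTable": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["key", "microbe", "immune", "F", "p", "pAdj", "cohortLines", "glyph"],
        "additionalProperties": false,
        "properties": {
          "key": {"type": "integer", "minimum": 1},
          "microbe": {"type": "string"},
          "immune": {"type": "string"},
          "F": {"type": "number", "minimum": 0},
          "p": {"type": "number", "minimum": 0, "maximum": 1},
          "pAdj": {"type": "number", "minimum": 0, "maximum": 1},
          "interactionP": {"type": "object", "patternProperties": {".*": {"type": "number", "minimum": 0, "maximum": 1}}},
          "maxInfluence": {"type": ["number", "null"], "minimum": 0},
          "cohortLines": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["cohort", "intercept", "slope", "xMin", "xMax"],
              "additionalProperties": false,
              "properties": {
                "cohort": {"type": "string"},
                "intercept": {"type": "number"},
                "slope": {"type": "number"},
                "xMin": {"type": "number"},
                "xMax": {"type": "number"}
              }
            }
          },
          "glyph": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["cohort", "x0", "y0", "x1", "y1"],
              "additionalProperties": false,
              "properties": {
                "cohort": {"type": "string"},
                "x0": {"type": "number", "minimum": 0, "maximum": 1},
                "y0": {"type": "number", "minimum": 0, "maximum": 1},
                "x1": {"type": "number", "minimum": 0, "maximum": 1},
                "y1": {"type": "number", "minimum": 0, "maximum": 1}
              }
            }
          }
        }
      }
    },
    "data": {
      "type": "object",
      "patternProperties": {
        "^[0-9]+$": {
          "type": "object",
          "required": ["x", "y", "cohort", "xUnits", "yUnits"],
          "additionalProperties": false,
          "properties": {
            "x": {"type": "array", "items": {"type": "number"}},
            "y": {"type": "array", "items": {"type": "number"}},
            "cohort": {"type": "array", "items": {"type": "string"}},
            "dffits": {"type": "array", "items": {"type": "number", "minimum": 0}},
            "xUnits": {"type": "string"},
            "yUnits": {"type": "string"}
          }
        }
      },
      "additionalProperties": false
    }
  }
}
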