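{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "swiss JSON report",
  "description": "Shape of the JSON reports written by the swiss CLI. All commands share the provenance block; the remaining fields depend on the subcommand.",
  "type": "object",
  "required": ["tool", "version", "config", "input_checksums"],
  "properties": {
    "tool": {"const": "swiss"},
    "version": {"type": "string"},
    "config": {
      "type": "object",
      "description": "Resolved configuration of the run, including the subcommand and every input path and flag.",
      "required": ["subcommand"],
      "properties": {"subcommand": {"enum": ["score", "compare", "perfect", "sweep", "simulate"]}}
    },
    "input_checksums": {
      "type": "object",
      "additionalProperties": {"type": "string", "pattern": "^[0-9a-f]{32}$"}
    },

    "sst": {"type": "number", "minimum": 0},
    "wiss": {"type": "number", "minimum": 0},
    "swiss": {"type": "number", "minimum": 0, "maximum": 1},
    "contributions": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0}
    },

    "method_a": {"type": "string"},
    "method_b": {"type": "string"},
    "swiss_a": {"type": "number", "minimum": 0, "maximum": 1},
    "swiss_b": {"type": "number", "minimum": 0, "maximum": 1},
    "p_better": {"type": "number", "minimum": 0, "maximum": 1},
    "p_worse": {"type": "number", "minimum": 0, "maximum": 1},
    "ci90": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 2,
      "maxItems": 2
    },
    "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "verdict": {"enum": ["A_better", "B_better", "no_significant_difference"]},
    "B": {"type": "integer", "minimum": 1},
    "seed": {"type": ["integer", "null"]},
    "exact": {"type": "boolean"},
    "null_scores": {"type": "array", "items": {"type": "number"}},

    "original_swiss": {"type": "number", "minimum": 0, "maximum": 1},
    "enhanced_swiss": {"type": "number", "minimum": 0, "maximum": 1},
    "per_class_values": {
      "type": "object",
      "description": "class -> [max, min] of that class's gene averages",
      "additionalProperties": {
        "type": "array",
        "items": {"type": "number"},
        "minItems": 2,
        "maxItems": 2
      }
    }
  }
}
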