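{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ahrfsig pipeline run configuration",
  "type": "object",
  "required": ["seed"],
  "additionalProperties": false,
  "properties": {
    "seed": {
      "type": "integer",
      "description": "Global seed; every stage seed derives from it deterministically."
    },
    "cohorts": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "mode": {"enum": ["synth", "files"], "default": "synth"},
        "synth": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "shared_informative": {"type": "integer", "minimum": 0, "default": 30},
            "a": {"$ref": "#/$defs/cohortSpec"},
            "b": {"$ref": "#/$defs/cohortSpec"}
          }
        },
        "files": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "a": {"$ref": "#/$defs/cohortFiles"},
            "b": {"$ref": "#/$defs/cohortFiles"}
          }
        }
      }
    },
    "preprocess": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "quantile": {"type": "boolean", "default": true},
        "batch": {"type": "boolean", "default": true}
      }
    },
    "stability": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_boot": {"type": "integer", "minimum": 1, "default": 100},
        "score_threshold": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "default": 0.6},
        "penalty_strength": {"type": "number", "exclusiveMinimum": 0, "default": 0.08},
        "stratified": {"type": "boolean", "default": true}
      }
    },
    "signature": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "top_k": {"type": "integer", "minimum": 1, "default": 1500},
        "step": {"type": "integer", "minimum": 1, "default": 10},
        "explicit_sizes": {
          "type": ["array", "null"],
          "items": {"type": "integer", "minimum": 1},
          "default": null
        },
        "l2_strength": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
        "ci_resamples": {"type": "integer", "minimum": 100, "default": 2000}
      }
    },
    "enrich": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "gmt": {"type": ["string", "null"], "default": null},
        "n_synth_sets": {"type": "integer", "minimum": 1, "default": 20}
      }
    },
    "network": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "sif": {"type": ["string", "null"], "default": null},
        "min_degree": {"type": "integer", "minimum": 1, "default": 10}
      }
    }
  },
  "$defs": {
    "cohortSpec": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_cases": {"type": "integer", "minimum": 1},
        "n_controls": {"type": "integer", "minimum": 1},
        "n_genes": {"type": "integer", "minimum": 1, "default": 5000},
        "n_informative": {"type": "integer", "minimum": 0, "default": 50},
        "effect_size": {"type": "number", "default": 1.0},
        "noise_sd": {"type": "number", "exclusiveMinimum": 0, "default": 0.5},
        "n_batches": {"type": "integer", "minimum": 1, "default": 1},
        "batch_shift_sd": {"type": "number", "minimum": 0, "default": 0.0}
      }
    },
    "cohortFiles": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "expression": {"type": ["string", "null"]},
        "labels": {"type": ["string", "null"]},
        "annotation": {"type": ["string", "null"]}
      }
    }
  }
}
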