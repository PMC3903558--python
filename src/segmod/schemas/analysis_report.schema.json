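{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ModelComparisonReport",
  "description": "Output of `segmod analyze` (segmod.inference.ModelComparison.to_dict).",
  "type": "object",
  "required": ["positions", "runs", "spacings", "k_hat", "fits", "verdict"],
  "properties": {
    "positions": {"type": "array", "items": {"type": "integer"}},
    "runs": {"type": "array", "items": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2}},
    "spacings": {"type": "array", "items": {"type": "integer"}},
    "k_hat": {"type": ["integer", "null"]},
    "k_hat_reason": {"type": ["string", "null"]},
    "fits": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["feasible", "k", "multiplicative_cost", "sequential_cost"],
        "properties": {
          "feasible": {"type": "boolean"},
          "k": {"type": "integer"},
          "anchor": {"type": ["integer", "null"]},
          "node": {"type": ["object", "null"]},
          "primary_block": {"type": ["array", "null"]},
          "multiplicative_cost": {"type": ["integer", "null"]},
          "sequential_cost": {"type": "integer"},
          "mismatches": {"type": "integer"}
        }
      }
    },
    "verdict": {"type": "string"},
    "best_k": {"type": ["integer", "null"]},
    "regenerated_diff": {"type": "array", "items": {"type": "integer"}}
  }
}
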