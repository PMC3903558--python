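{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SplittingSpec",
  "description": "Parameters of the multiplicative segmentation model. Validation is enforced in code (segmod.splitting_model.SplittingSpec.from_dict); this file documents the format.",
  "type": "object",
  "required": ["taxon_profile", "k", "P", "t"],
  "additionalProperties": false,
  "properties": {
    "taxon_profile": {"enum": ["julidan", "polydesmidan"]},
    "k": {"type": "integer", "minimum": 0, "description": "binary splitting cycles per primary segment"},
    "P": {"type": "integer", "minimum": 1, "description": "realized primary segments"},
    "t": {"type": "integer", "minimum": 0, "description": "anterior truncation; must be < 2**k"},
    "markers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ps", "depth", "index"],
        "properties": {
          "ps": {"type": "integer", "minimum": 1},
          "depth": {"type": "integer", "minimum": 0},
          "index": {"type": "integer", "minimum": 0}
        }
      }
    },
    "anterior_marker_positions": {
      "type": "array",
      "items": {"type": "integer", "minimum": 1}
    }
  }
}
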