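{
  "$comment": "Schema of the per-run pipeline report emitted by radsurv.pipeline; mirrored by radsurv.pipeline.REPORT_SCHEMA and enforced by validate_report().",
  "type": "object",
  "required": ["mode", "seed", "train_ids", "test_ids", "outcomes"],
  "properties": {
    "mode": {"type": "string", "enum": ["deep", "handcrafted"]},
    "seed": {"type": "integer"},
    "channel_mode": {"type": "string", "enum": ["slices", "scales"]},
    "train_ids": {"type": "array", "items": {"type": "string"}},
    "test_ids": {"type": "array", "items": {"type": "string"}},
    "outcomes": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["selected", "coefficients", "hazard_ratios",
                     "p_values", "c_index", "cutoffs", "km"],
        "properties": {
          "selected": {"type": "array", "items": {"type": "string"}},
          "coefficients": {"type": "object"},
          "hazard_ratios": {"type": "object"},
          "p_values": {"type": "object"},
          "c_index": {"type": ["number", "null"]},
          "cutoffs": {"type": "object"},
          "km": {"type": "object"}
        }
      }
    }
  }
}
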