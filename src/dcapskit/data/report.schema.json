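{
  "type": "object",
  "required": ["schema_version", "mode", "config", "results"],
  "properties": {
    "schema_version": {"type": "integer"},
    "mode": {"type": "string"},
    "config": {"type": "object"},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "results": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["enzyme", "motif", "orientation", "mismatch_count"],
        "properties": {
          "enzyme": {"type": "string"},
          "motif": {"type": "string"},
          "orientation": {"type": "string"},
          "mismatch_count": {"type": "integer"},
          "primer": {"type": "string"},
          "primer_length": {"type": "integer"},
          "tm_celsius": {"type": "number"},
          "mismatch_positions": {"type": "array", "items": {"type": "integer"}},
          "is_caps": {"type": "boolean"},
          "loss_fraction": {"type": "number"}
        }
      }
    }
  }
}
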