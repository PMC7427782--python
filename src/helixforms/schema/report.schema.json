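{
  "type": "object",
  "required": ["provenance", "chains", "comparisons", "errors", "coordination"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["inputs", "config_hash", "tool_version", "timestamp"],
      "properties": {
        "inputs": {"type": "array", "items": {"type": "string"}},
        "config_hash": {"type": "string"},
        "tool_version": {"type": "string"},
        "timestamp": {"type": "string"}
      }
    },
    "chains": {"type": "object"},
    "comparisons": {"type": "object"},
    "errors": {"type": "object"},
    "coordination": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["structure", "metal", "atoms"],
        "properties": {
          "structure": {"type": "string"},
          "metal": {"type": "string"},
          "atoms": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["chain", "residue", "atom", "distance"],
              "properties": {"distance": {"type": "number"}}
            }
          }
        }
      }
    }
  }
}
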