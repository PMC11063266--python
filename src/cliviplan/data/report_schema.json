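{
  "type": "object",
  "required": ["tool", "provenance", "coefficients", "plans", "winner"],
  "properties": {
    "tool": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "provenance": {"type": "object"},
    "coefficients": {"type": "object"},
    "plans": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["plan_id", "approach_label", "rank", "total_weight",
                     "injury_risk_sum", "surgical_freedom_sum", "paths"],
        "properties": {
          "plan_id": {"type": "string"},
          "approach_label": {"type": "string"},
          "rank": {"type": "integer"},
          "total_weight": {"type": "number"},
          "injury_risk_sum": {"type": "number"},
          "surgical_freedom_sum": {"type": "number"},
          "paths": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["path_id", "tissue_volumes_mm3", "injury_risk",
                           "surgical_freedom", "weight"],
              "properties": {
                "path_id": {"type": "string"},
                "tissue_volumes_mm3": {"type": "object"},
                "injury_risk": {"type": "number"},
                "surgical_freedom": {"type": "number"},
                "weight": {"type": "number"}
              }
            }
          }
        }
      }
    },
    "winner": {
      "type": "object",
      "required": ["plan_id", "approach_label", "total_weight"],
      "properties": {
        "plan_id": {"type": "string"},
        "approach_label": {"type": "string"},
        "total_weight": {"type": "number"}
      }
    }
  }
}
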