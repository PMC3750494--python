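{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/mvnet/network.schema.json",
  "title": "mvnet network document",
  "description": "Declarative definition of a multi-valued logical regulatory network: nodes with initial states, thresholds and optional clamps; signed weighted edges with optional source gates and dependency conditions. The YAML dialect is the same tree.",
  "type": "object",
  "required": ["U", "nodes"],
  "properties": {
    "format_version": {"type": "string"},
    "U": {"type": "integer", "minimum": 1},
    "metadata": {"type": "object"},
    "nodes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "kind": {"enum": ["rna", "protein", "complex", "event", "checkpoint", "signal"]},
          "initial": {"type": "integer", "minimum": 0},
          "threshold_plus": {"type": "integer"},
          "threshold_minus": {"type": "integer"},
          "clamp": {"type": "integer", "minimum": 0},
          "note": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "weight"],
        "properties": {
          "source": {"type": "string"},
          "target": {"type": "string"},
          "weight": {"type": "integer", "not": {"const": 0}},
          "gate": {"type": "integer", "minimum": 0},
          "depends": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["node"],
              "properties": {
                "node": {"type": "string"},
                "when": {"enum": ["active", "inactive"]}
              },
              "additionalProperties": false
            }
          },
          "note": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
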