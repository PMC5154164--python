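{
  "type": "object",
  "required": ["elements", "style"],
  "additionalProperties": false,
  "properties": {
    "elements": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group", "data"],
        "properties": {
          "group": {"type": "string", "enum": ["nodes", "edges"]},
          "data": {
            "type": "object",
            "required": ["id", "kind"],
            "properties": {
              "id": {"type": "string"},
              "label": {"type": "string"},
              "kind": {"type": "string"},
              "ref": {"type": "string"},
              "source": {"type": "string"},
              "target": {"type": "string"},
              "color": {"type": "string"}
            }
          },
          "position": {
            "type": "object",
            "required": ["x", "y"],
            "additionalProperties": false,
            "properties": {
              "x": {"type": "number"},
              "y": {"type": "number"}
            }
          }
        }
      }
    },
    "style": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["selector", "style"],
        "additionalProperties": false,
        "properties": {
          "selector": {"type": "string"},
          "style": {"type": "object"}
        }
      }
    }
  }
}
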