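{
  "type": "object",
  "required": ["schema_version", "compounds", "reactions", "pathways"],
  "additionalProperties": false,
  "properties": {
    "schema_version": {"type": "string"},
    "compounds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "participants"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "direction": {"type": "string", "enum": ["forward", "reversible"]},
          "enzyme_labels": {"type": "array", "items": {"type": "string"}},
          "gene_ids": {"type": "array", "items": {"type": "string"}},
          "participants": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["compound_id", "side", "role"],
              "additionalProperties": false,
              "properties": {
                "compound_id": {"type": "string"},
                "side": {"type": "string", "enum": ["substrate", "product"]},
                "role": {"type": "string", "enum": ["main", "side"]},
                "coefficient": {"type": "number"}
              }
            }
          }
        }
      }
    },
    "pathways": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "reaction_ids"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "reaction_ids": {"type": "array", "items": {"type": "string"}},
          "links": {
            "type": "array",
            "items": {"type": "array", "items": {"type": "string"}, "minItems": 2}
          },
          "class_path": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
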