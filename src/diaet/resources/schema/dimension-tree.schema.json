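{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://w3id.org/diaet/dimension-tree.schema.json",
  "title": "Dimension tree configuration",
  "description": "Weighted hierarchy of comparison dimensions. Inner nodes carry children; leaves bind a superiority criterion. Sibling weights need not sum to one (aggregation normalizes).",
  "$ref": "#/$defs/node",
  "$defs": {
    "node": {
      "type": "object",
      "required": ["id"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "label": {"type": "string"},
        "weight": {"type": "number", "minimum": 0, "default": 1},
        "children": {
          "type": "array",
          "minItems": 1,
          "items": {"$ref": "#/$defs/node"}
        },
        "criterion": {"enum": ["efficacy", "safety"]},
        "target": {"type": "string", "minLength": 1},
        "direction": {"enum": ["decrease", "increase"]}
      },
      "oneOf": [
        {"required": ["children"]},
        {"required": ["criterion", "target"]}
      ]
    }
  }
}
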