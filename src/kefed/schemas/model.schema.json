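{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/kefed/model.schema.json",
  "title": "KEfED model document",
  "type": "object",
  "required": ["id", "nodes", "edges"],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "name": {"type": "string"},
    "description": {"type": "string"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "kind": {
            "enum": ["activity", "material", "parameter", "constant", "measurement", "branch", "fork"]
          },
          "label": {"type": "string"},
          "ontology_term": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_.\\-]*:\\S+$"},
          "domain": {
            "type": "object",
            "required": ["kind"],
            "properties": {
              "kind": {"enum": ["nominal", "ordinal", "free_text", "region_extent", "numeric"]},
              "levels": {"type": "array", "items": {"type": "string"}},
              "units": {"type": "string"}
            },
            "additionalProperties": false
          }
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "kind"],
        "properties": {
          "source": {"type": "string", "minLength": 1},
          "target": {"type": "string", "minLength": 1},
          "kind": {"enum": ["flow", "parameter_of", "measurement_of"]}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
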