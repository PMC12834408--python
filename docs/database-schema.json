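{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "gerotcm native TCM database document",
  "type": "object",
  "required": ["compounds", "herbs", "formulas"],
  "properties": {
    "compounds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["compound_id", "targets"],
        "properties": {
          "compound_id": {"type": "string"},
          "name": {"type": "string"},
          "targets": {
            "type": "array",
            "items": {"type": "string"},
            "description": "Protein-target gene symbols (uppercased on load)"
          }
        }
      }
    },
    "herbs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["herb_id", "compounds"],
        "properties": {
          "herb_id": {"type": "string"},
          "pinyin_name": {"type": "string"},
          "compounds": {
            "type": "array",
            "items": {"type": "string"},
            "description": "compound_id references; must resolve"
          },
          "temperature": {
            "enum": ["hot", "warm", "neutral", "cool", "cold", null],
            "description": "null means unknown, never assumed neutral"
          },
          "tastes": {"type": ["array", "null"], "items": {"type": "string"}},
          "meridians": {"type": ["array", "null"], "items": {"type": "string"}},
          "toxicity_flags": {
            "type": "array",
            "items": {"type": "string"},
            "description": "e.g. \"contains:aconitine\"; matched against the composer blocklist"
          },
          "animal_derived": {"type": ["boolean", "null"]},
          "contraindication_tags": {
            "type": "array",
            "items": {"type": "string"},
            "description": "lowercase condition labels matched against patient conditions"
          }
        }
      }
    },
    "formulas": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["formula_id", "herbs"],
        "properties": {
          "formula_id": {"type": "string"},
          "name": {"type": "string"},
          "herbs": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string"},
            "description": "herb_id references; must resolve"
          },
          "source_text": {"type": ["string", "null"]}
        }
      }
    }
  }
}
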