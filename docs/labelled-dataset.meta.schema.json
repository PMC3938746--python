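{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "odmconvert labelled-dataset metadata sidecar",
  "description": "Sidecar written next to the CSV data table by odmconvert.stats.save_stats; everything needed to rebuild the study model losslessly.",
  "type": "object",
  "required": ["format", "version", "language", "study_attributes", "variables"],
  "properties": {
    "format": {"const": "odmconvert-labelled-dataset"},
    "version": {"type": "integer", "minimum": 1},
    "language": {"type": "string", "description": "primary display language (BCP-47 short tag)"},
    "languages": {"type": "array", "items": {"type": "string"}},
    "n_rows": {"type": "integer", "minimum": 0},
    "study_attributes": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "StudyOID, StudyName, StudyDescription, Sponsor, Condition, Form, FirstName, LastName, Organization"
    },
    "groups": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "labels": {"type": "object", "additionalProperties": {"type": "string"}},
          "codes": {"$ref": "#/definitions/codes"}
        }
      }
    },
    "variables": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["oid", "storage"],
        "properties": {
          "oid": {"type": "string", "description": "item OID; equals the CSV column header"},
          "storage": {"enum": ["logical", "integer", "real", "text"]},
          "datatype": {
            "enum": ["boolean", "integer", "date", "float", "string", "time", null],
            "description": "original item datatype, so date/time/string (all stored as text) invert unambiguously"
          },
          "name": {"type": "string"},
          "label": {"type": "string"},
          "labels": {"type": "object", "additionalProperties": {"type": "string"}},
          "codes": {"$ref": "#/definitions/codes"},
          "group": {"type": ["string", "null"]},
          "codelist_oid": {"type": ["string", "null"]},
          "value_labels": {
            "type": ["object", "null"],
            "additionalProperties": {"type": "string"},
            "description": "coded value -> decode text in the primary language; coded values are text even for integer items"
          },
          "value_decodes": {
            "type": ["object", "null"],
            "additionalProperties": {"type": "object", "additionalProperties": {"type": "string"}}
          },
          "value_codes": {
            "type": ["object", "null"],
            "additionalProperties": {"$ref": "#/definitions/codes"}
          }
        }
      }
    }
  },
  "definitions": {
    "codes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["terminology", "code"],
        "properties": {
          "terminology": {"type": "string"},
          "code": {"type": "string"}
        }
      }
    }
  }
}
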