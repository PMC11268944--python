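{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://sdmkit.readthedocs.io/schema/reading-1.0.json",
  "title": "sdmkit canonical reading",
  "description": "One subject's one session of one structured test: metadata, ordered levels with columnar timestamped datasets, epochs, measures and flags. Timestamps are seconds (float) relative to reading start.",
  "type": "object",
  "required": ["metadata", "levels"],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["evaluation_code", "subject_id", "session_id"],
      "properties": {
        "evaluation_code": {"$ref": "#/$defs/slug"},
        "subject_id": {"type": "string"},
        "session_id": {"type": "string"},
        "schema_version": {"type": "string"},
        "device": {"$ref": "#/$defs/source"}
      }
    },
    "levels": {"type": "array", "items": {"$ref": "#/$defs/level"}},
    "measures": {"type": "array", "items": {"$ref": "#/$defs/measure"}},
    "flags": {"type": "array", "items": {"$ref": "#/$defs/flag"}}
  },
  "$defs": {
    "slug": {"type": "string", "pattern": "^[a-z0-9_]+(-[a-z0-9_]+)*$"},
    "source": {
      "type": "object",
      "properties": {
        "device_model": {"type": "string"},
        "sensor": {"type": "string"},
        "sampling_freq": {"type": ["number", "null"]},
        "placement": {"enum": ["handheld", "belt", "none"]}
      }
    },
    "definition": {
      "type": "object",
      "required": ["id", "name"],
      "properties": {
        "id": {"$ref": "#/$defs/slug"},
        "name": {"type": "string"},
        "unit": {"type": "string"},
        "data_type": {"enum": ["float", "int", "bool", "string", "timestamp"]},
        "valid_range": {
          "type": ["array", "null"],
          "items": {"type": "number"},
          "minItems": 2,
          "maxItems": 2
        }
      }
    },
    "level": {
      "type": "object",
      "required": ["id", "datasets"],
      "properties": {
        "id": {"$ref": "#/$defs/slug"},
        "modalities": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["dimension", "value"],
            "properties": {
              "dimension": {"$ref": "#/$defs/slug"},
              "value": {"$ref": "#/$defs/slug"}
            }
          }
        },
        "start": {"type": "number"},
        "end": {"type": "number"},
        "context": {"type": "object"},
        "datasets": {"type": "array", "items": {"$ref": "#/$defs/dataset"}},
        "epochs": {"type": "array", "items": {"$ref": "#/$defs/epoch"}},
        "measures": {"type": "array", "items": {"$ref": "#/$defs/measure"}}
      }
    },
    "dataset": {
      "type": "object",
      "required": ["id", "columns", "values"],
      "properties": {
        "id": {"$ref": "#/$defs/slug"},
        "source": {"$ref": "#/$defs/source"},
        "columns": {
          "type": "array",
          "minItems": 1,
          "items": {"$ref": "#/$defs/definition"}
        },
        "values": {"type": "array", "items": {"type": "array"}}
      }
    },
    "epoch": {
      "type": "object",
      "required": ["definition", "start", "end"],
      "properties": {
        "definition": {"$ref": "#/$defs/definition"},
        "start": {"type": "number"},
        "end": {"type": "number"},
        "payload": {"type": "object"}
      }
    },
    "measure": {
      "type": "object",
      "required": ["definition", "value"],
      "properties": {
        "definition": {"$ref": "#/$defs/definition"},
        "value": {}
      }
    },
    "flag": {
      "type": "object",
      "required": ["id", "reason"],
      "properties": {
        "id": {
          "type": "string",
          "pattern": "^[a-z0-9_]+-(technical|behavioral)-(deviation|invalidation)-[a-z0-9_]+$"
        },
        "reason": {"type": "string"},
        "stopped_processing": {"type": "boolean"},
        "targets": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["kind"],
            "properties": {
              "kind": {"enum": ["reading", "level", "dataset", "epoch", "measure"]},
              "level_id": {"type": ["string", "null"]},
              "item_id": {"type": ["string", "null"]}
            }
          }
        }
      }
    }
  }
}
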