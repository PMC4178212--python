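{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fluxcue metabolic model dialect",
  "type": "object",
  "required": ["metabolites", "reactions"],
  "properties": {
    "metabolites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "compartment": {"type": "string", "minLength": 1}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "stoich"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "stoich": {
            "type": "object",
            "minProperties": 1,
            "additionalProperties": {"type": "number"},
            "description": "metabolite id -> signed coefficient; negative = consumed"
          },
          "lb": {"type": "number", "default": 0},
          "ub": {"type": "number", "default": 1000},
          "gpr": {
            "type": "string",
            "description": "boolean rule over gene ids with and/or and parentheses; empty = none"
          },
          "pathway": {"type": "string", "description": "subsystem label; empty = unassigned"},
          "exchange": {"type": "boolean", "default": false}
        }
      }
    }
  }
}
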