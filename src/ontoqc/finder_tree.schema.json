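{
  "$defs": {
    "FinderNode": {
      "properties": {
        "children": {
          "default": [],
          "items": {
            "$ref": "#/$defs/FinderNode"
          },
          "title": "Children",
          "type": "array"
        },
        "count": {
          "title": "Count",
          "type": "integer"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "repeat": {
          "default": false,
          "title": "Repeat",
          "type": "boolean"
        }
      },
      "required": [
        "id",
        "label",
        "count"
      ],
      "title": "FinderNode",
      "type": "object"
    }
  },
  "properties": {
    "meta": {
      "additionalProperties": true,
      "title": "Meta",
      "type": "object"
    },
    "roots": {
      "items": {
        "$ref": "#/$defs/FinderNode"
      },
      "title": "Roots",
      "type": "array"
    }
  },
  "required": [
    "meta",
    "roots"
  ],
  "title": "FinderTree",
  "type": "object"
}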