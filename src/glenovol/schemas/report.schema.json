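{
  "$defs": {
    "CorrelationCell": {
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "p": {
          "title": "P",
          "type": "number"
        },
        "r": {
          "title": "R",
          "type": "number"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        }
      },
      "required": [
        "r",
        "p",
        "n",
        "significant"
      ],
      "title": "CorrelationCell",
      "type": "object"
    },
    "ICCReport": {
      "properties": {
        "category": {
          "title": "Category",
          "type": "string"
        },
        "model": {
          "title": "Model",
          "type": "string"
        },
        "n_raters": {
          "title": "N Raters",
          "type": "integer"
        },
        "n_subjects": {
          "title": "N Subjects",
          "type": "integer"
        },
        "value": {
          "title": "Value",
          "type": "number"
        }
      },
      "required": [
        "value",
        "model",
        "category",
        "n_subjects",
        "n_raters"
      ],
      "title": "ICCReport",
      "type": "object"
    },
    "SummaryRow": {
      "properties": {
        "max": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Max"
        },
        "mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mean"
        },
        "min": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Min"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "sd": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sd"
        },
        "variable": {
          "title": "Variable",
          "type": "string"
        }
      },
      "required": [
        "variable",
        "n"
      ],
      "title": "SummaryRow",
      "type": "object"
    }
  },
  "description": "Top-level report: descriptives, correlation grid, optional reliability.",
  "properties": {
    "correlations": {
      "additionalProperties": {
        "additionalProperties": {
          "$ref": "#/$defs/CorrelationCell"
        },
        "type": "object"
      },
      "title": "Correlations",
      "type": "object"
    },
    "descriptives": {
      "items": {
        "$ref": "#/$defs/SummaryRow"
      },
      "title": "Descriptives",
      "type": "array"
    },
    "iccs": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/ICCReport"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Iccs"
    },
    "n_patients": {
      "title": "N Patients",
      "type": "integer"
    },
    "notes": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Notes",
      "type": "array"
    },
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    }
  },
  "required": [
    "n_patients",
    "descriptives",
    "correlations"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
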