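{
  "$defs": {
    "CrosstabModel": {
      "additionalProperties": false,
      "properties": {
        "quartile": {
          "title": "Quartile",
          "type": "string"
        },
        "n_in_quartile": {
          "title": "N In Quartile",
          "type": "integer"
        },
        "thresholds": {
          "items": {
            "type": "integer"
          },
          "title": "Thresholds",
          "type": "array"
        },
        "fractions": {
          "items": {
            "type": "number"
          },
          "title": "Fractions",
          "type": "array"
        }
      },
      "required": [
        "quartile",
        "n_in_quartile",
        "thresholds",
        "fractions"
      ],
      "title": "CrosstabModel",
      "type": "object"
    },
    "LevelAnalysis": {
      "additionalProperties": false,
      "properties": {
        "spearman": {
          "$ref": "#/$defs/SpearmanModel"
        },
        "passing_bablok": {
          "$ref": "#/$defs/PassingBablokModel"
        }
      },
      "required": [
        "spearman",
        "passing_bablok"
      ],
      "title": "LevelAnalysis",
      "type": "object"
    },
    "PassingBablokModel": {
      "additionalProperties": false,
      "properties": {
        "slope": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Slope"
        },
        "intercept": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Intercept"
        },
        "slope_ci_low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Slope Ci Low"
        },
        "slope_ci_high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Slope Ci High"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "n_slopes": {
          "title": "N Slopes",
          "type": "integer"
        },
        "k_offset": {
          "title": "K Offset",
          "type": "integer"
        },
        "level": {
          "title": "Level",
          "type": "number"
        }
      },
      "required": [
        "slope",
        "intercept",
        "slope_ci_low",
        "slope_ci_high",
        "n_pairs",
        "n_slopes",
        "k_offset",
        "level"
      ],
      "title": "PassingBablokModel",
      "type": "object"
    },
    "SpearmanModel": {
      "additionalProperties": false,
      "properties": {
        "r": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "R"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "ci_low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ci Low"
        },
        "ci_high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ci High"
        },
        "level": {
          "title": "Level",
          "type": "number"
        }
      },
      "required": [
        "r",
        "n",
        "ci_low",
        "ci_high",
        "level"
      ],
      "title": "SpearmanModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Machine-readable pipeline output mirroring the exclusion flowchart.",
  "properties": {
    "n_total_periods": {
      "title": "N Total Periods",
      "type": "integer"
    },
    "n_cfu_discarded": {
      "title": "N Cfu Discarded",
      "type": "integer"
    },
    "n_distorted": {
      "title": "N Distorted",
      "type": "integer"
    },
    "n_analyzed": {
      "title": "N Analyzed",
      "type": "integer"
    },
    "period_level_excluded": {
      "$ref": "#/$defs/LevelAnalysis"
    },
    "period_level_retained": {
      "$ref": "#/$defs/LevelAnalysis"
    },
    "surgery_level_excluded": {
      "$ref": "#/$defs/LevelAnalysis"
    },
    "surgery_level_retained": {
      "$ref": "#/$defs/LevelAnalysis"
    },
    "crosstab_lowest": {
      "$ref": "#/$defs/CrosstabModel"
    },
    "crosstab_highest": {
      "$ref": "#/$defs/CrosstabModel"
    }
  },
  "required": [
    "n_total_periods",
    "n_cfu_discarded",
    "n_distorted",
    "n_analyzed",
    "period_level_excluded",
    "period_level_retained",
    "surgery_level_excluded",
    "surgery_level_retained",
    "crosstab_lowest",
    "crosstab_highest"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
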