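{
  "$defs": {
    "BalanceSection": {
      "properties": {
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "features": {
          "items": {
            "type": "string"
          },
          "title": "Features",
          "type": "array"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "n_unmatched_treated": {
          "title": "N Unmatched Treated",
          "type": "integer"
        },
        "smd_after": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Smd After",
          "type": "object"
        },
        "smd_before": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Smd Before",
          "type": "object"
        }
      },
      "required": [
        "features",
        "n_pairs",
        "n_unmatched_treated",
        "converged"
      ],
      "title": "BalanceSection",
      "type": "object"
    },
    "MatchingParams": {
      "properties": {
        "cutoff": {
          "title": "Cutoff",
          "type": "number"
        },
        "filters": {
          "items": {
            "type": "string"
          },
          "title": "Filters",
          "type": "array"
        },
        "gene_subset": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gene Subset"
        },
        "level": {
          "title": "Level",
          "type": "string"
        }
      },
      "required": [
        "level",
        "cutoff"
      ],
      "title": "MatchingParams",
      "type": "object"
    },
    "MatchingSection": {
      "properties": {
        "dt_positive": {
          "items": {
            "type": "string"
          },
          "title": "Dt Positive",
          "type": "array"
        },
        "n_dt_negative": {
          "title": "N Dt Negative",
          "type": "integer"
        },
        "n_dt_positive": {
          "title": "N Dt Positive",
          "type": "integer"
        },
        "n_scored": {
          "title": "N Scored",
          "type": "integer"
        },
        "params": {
          "$ref": "#/$defs/MatchingParams"
        },
        "score_summary": {
          "$ref": "#/$defs/ScoreSummary"
        }
      },
      "required": [
        "params",
        "n_scored",
        "n_dt_positive",
        "n_dt_negative",
        "dt_positive",
        "score_summary"
      ],
      "title": "MatchingSection",
      "type": "object"
    },
    "ProfileSummary": {
      "properties": {
        "case_id": {
          "title": "Case Id",
          "type": "string"
        },
        "n_key": {
          "title": "N Key",
          "type": "integer"
        },
        "n_total": {
          "title": "N Total",
          "type": "integer"
        },
        "n_vus": {
          "title": "N Vus",
          "type": "integer"
        }
      },
      "required": [
        "case_id",
        "n_key",
        "n_vus",
        "n_total"
      ],
      "title": "ProfileSummary",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "inputs": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Inputs",
          "type": "object"
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
        },
        "version": {
          "default": "0.1.0",
          "title": "Version",
          "type": "string"
        }
      },
      "title": "Provenance",
      "type": "object"
    },
    "ScoreSummary": {
      "properties": {
        "maximum": {
          "title": "Maximum",
          "type": "number"
        },
        "median": {
          "title": "Median",
          "type": "number"
        },
        "minimum": {
          "title": "Minimum",
          "type": "number"
        }
      },
      "required": [
        "minimum",
        "median",
        "maximum"
      ],
      "title": "ScoreSummary",
      "type": "object"
    }
  },
  "properties": {
    "balance": {
      "anyOf": [
        {
          "$ref": "#/$defs/BalanceSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "case_id": {
      "title": "Case Id",
      "type": "string"
    },
    "comparisons": {
      "anyOf": [
        {
          "additionalProperties": {
            "items": {
              "additionalProperties": true,
              "type": "object"
            },
            "type": "array"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Comparisons"
    },
    "enrichment": {
      "anyOf": [
        {
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Enrichment"
    },
    "matching": {
      "$ref": "#/$defs/MatchingSection"
    },
    "profile": {
      "$ref": "#/$defs/ProfileSummary"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "trials": {
      "anyOf": [
        {
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Trials"
    }
  },
  "required": [
    "case_id",
    "profile",
    "matching",
    "provenance"
  ],
  "title": "CommunityReport",
  "type": "object"
}
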