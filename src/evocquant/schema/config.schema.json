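{
  "$defs": {
    "CohortSimConfig": {
      "additionalProperties": false,
      "properties": {
        "baseline_ocn_mean": {
          "default": 47595.2,
          "title": "Baseline Ocn Mean",
          "type": "number"
        },
        "baseline_ocn_sd": {
          "default": 3617.6,
          "title": "Baseline Ocn Sd",
          "type": "number"
        },
        "days": {
          "items": {
            "type": "integer"
          },
          "title": "Days",
          "type": "array"
        },
        "n_samples": {
          "default": 12,
          "title": "N Samples",
          "type": "integer"
        },
        "pi_curve": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Pi Curve"
        },
        "pi_sd": {
          "default": 6.0,
          "title": "Pi Sd",
          "type": "number"
        },
        "sample_effect_sd": {
          "default": 0.05,
          "title": "Sample Effect Sd",
          "type": "number"
        },
        "stromal_survival": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Stromal Survival"
        },
        "tumor_fraction_mean": {
          "default": 0.8533,
          "title": "Tumor Fraction Mean",
          "type": "number"
        },
        "tumor_survival": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tumor Survival"
        }
      },
      "title": "CohortSimConfig",
      "type": "object"
    },
    "DetectionConfig": {
      "additionalProperties": false,
      "properties": {
        "cell_expansion_um": {
          "default": 3.0,
          "title": "Cell Expansion Um",
          "type": "number"
        },
        "dab_od_threshold": {
          "default": 0.15,
          "title": "Dab Od Threshold",
          "type": "number"
        },
        "h_od_threshold": {
          "default": 0.1,
          "title": "H Od Threshold",
          "type": "number"
        },
        "max_radius_um": {
          "default": 10.0,
          "title": "Max Radius Um",
          "type": "number"
        },
        "min_radius_um": {
          "default": 5.0,
          "title": "Min Radius Um",
          "type": "number"
        },
        "pixel_size_um": {
          "default": 0.5,
          "title": "Pixel Size Um",
          "type": "number"
        },
        "smoothing_sigma_um": {
          "default": 1.0,
          "title": "Smoothing Sigma Um",
          "type": "number"
        },
        "splitting_threshold": {
          "default": 0.15,
          "title": "Splitting Threshold",
          "type": "number"
        }
      },
      "title": "DetectionConfig",
      "type": "object"
    },
    "SimulationConfig": {
      "additionalProperties": false,
      "properties": {
        "cohort": {
          "$ref": "#/$defs/CohortSimConfig"
        },
        "tile": {
          "$ref": "#/$defs/TileSimConfig"
        }
      },
      "title": "SimulationConfig",
      "type": "object"
    },
    "StainConfig": {
      "additionalProperties": false,
      "properties": {
        "dab": {
          "items": {
            "type": "number"
          },
          "title": "Dab",
          "type": "array"
        },
        "hematoxylin": {
          "items": {
            "type": "number"
          },
          "title": "Hematoxylin",
          "type": "array"
        },
        "name": {
          "default": "h-dab-default",
          "title": "Name",
          "type": "string"
        },
        "residual": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Residual"
        }
      },
      "title": "StainConfig",
      "type": "object"
    },
    "StatisticsConfig": {
      "additionalProperties": false,
      "properties": {
        "posthoc_method": {
          "default": "bonferroni_paired_t",
          "title": "Posthoc Method",
          "type": "string"
        },
        "sphericity_alpha": {
          "default": 0.05,
          "title": "Sphericity Alpha",
          "type": "number"
        }
      },
      "title": "StatisticsConfig",
      "type": "object"
    },
    "TileSimConfig": {
      "additionalProperties": false,
      "properties": {
        "dab_od_neg_mean": {
          "default": 0.03,
          "title": "Dab Od Neg Mean",
          "type": "number"
        },
        "dab_od_pos_mean": {
          "default": 0.6,
          "title": "Dab Od Pos Mean",
          "type": "number"
        },
        "dab_od_pos_sd": {
          "default": 0.08,
          "title": "Dab Od Pos Sd",
          "type": "number"
        },
        "h_od_mean": {
          "default": 0.8,
          "title": "H Od Mean",
          "type": "number"
        },
        "h_od_sd": {
          "default": 0.05,
          "title": "H Od Sd",
          "type": "number"
        },
        "min_separation_um": {
          "default": 25.0,
          "title": "Min Separation Um",
          "type": "number"
        },
        "n_nuclei": {
          "default": 40,
          "title": "N Nuclei",
          "type": "integer"
        },
        "noise_sd": {
          "default": 0.0,
          "title": "Noise Sd",
          "type": "number"
        },
        "pixel_size_um": {
          "default": 0.5,
          "title": "Pixel Size Um",
          "type": "number"
        },
        "positive_fraction": {
          "default": 0.5,
          "title": "Positive Fraction",
          "type": "number"
        },
        "radius_um_range": {
          "items": {
            "type": "number"
          },
          "title": "Radius Um Range",
          "type": "array"
        },
        "tile_px": {
          "items": {
            "type": "integer"
          },
          "title": "Tile Px",
          "type": "array"
        }
      },
      "title": "TileSimConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level validated configuration of the whole pipeline.",
  "properties": {
    "detection": {
      "$ref": "#/$defs/DetectionConfig"
    },
    "schedule": {
      "items": {
        "type": "integer"
      },
      "title": "Schedule",
      "type": "array"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "simulation": {
      "$ref": "#/$defs/SimulationConfig"
    },
    "stains": {
      "$ref": "#/$defs/StainConfig"
    },
    "statistics": {
      "$ref": "#/$defs/StatisticsConfig"
    },
    "white_point": {
      "default": 255.0,
      "title": "White Point",
      "type": "number"
    }
  },
  "title": "PipelineConfig",
  "type": "object"
}
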