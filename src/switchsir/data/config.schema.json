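{
  "$defs": {
    "InitialConfig": {
      "additionalProperties": false,
      "properties": {
        "S0": {
          "exclusiveMinimum": 0,
          "title": "S0",
          "type": "number"
        },
        "I0": {
          "minimum": 0,
          "title": "I0",
          "type": "number"
        },
        "r0": {
          "default": 1,
          "minimum": 1,
          "title": "R0",
          "type": "integer"
        }
      },
      "required": [
        "S0",
        "I0"
      ],
      "title": "InitialConfig",
      "type": "object"
    },
    "ModelConfig": {
      "additionalProperties": false,
      "properties": {
        "regimes": {
          "items": {
            "$ref": "#/$defs/RegimeConfig"
          },
          "minItems": 1,
          "title": "Regimes",
          "type": "array"
        },
        "generator": {
          "items": {
            "items": {
              "type": "number"
            },
            "type": "array"
          },
          "title": "Generator",
          "type": "array"
        },
        "h": {
          "exclusiveMinimum": 0,
          "title": "H",
          "type": "number"
        },
        "l": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "L"
        }
      },
      "required": [
        "regimes",
        "generator",
        "h"
      ],
      "title": "ModelConfig",
      "type": "object"
    },
    "NumericsConfig": {
      "additionalProperties": false,
      "description": "Simulation controls; defaults match the reference experiment\n(horizon t = 1000).",
      "properties": {
        "T": {
          "default": 1000.0,
          "exclusiveMinimum": 0,
          "title": "T",
          "type": "number"
        },
        "dt": {
          "default": 0.01,
          "exclusiveMinimum": 0,
          "title": "Dt",
          "type": "number"
        },
        "n_paths": {
          "default": 200,
          "minimum": 1,
          "title": "N Paths",
          "type": "integer"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        },
        "extinction_floor": {
          "default": 0.0001,
          "exclusiveMinimum": 0,
          "title": "Extinction Floor",
          "type": "number"
        },
        "hist_bins": {
          "default": 40,
          "minimum": 2,
          "title": "Hist Bins",
          "type": "integer"
        },
        "hist_s_range": {
          "default": [
            0.0,
            3.5
          ],
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Hist S Range",
          "type": "array"
        },
        "hist_i_range": {
          "default": [
            0.0,
            3.5
          ],
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Hist I Range",
          "type": "array"
        },
        "window": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Window"
        }
      },
      "title": "NumericsConfig",
      "type": "object"
    },
    "OutputsConfig": {
      "additionalProperties": false,
      "properties": {
        "trajectory_csv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Trajectory Csv"
        },
        "summary_json": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Summary Json"
        }
      },
      "title": "OutputsConfig",
      "type": "object"
    },
    "RegimeConfig": {
      "additionalProperties": false,
      "description": "One regime's rate constants (see RegimeParameters for units).",
      "properties": {
        "Lambda": {
          "exclusiveMinimum": 0,
          "title": "Lambda",
          "type": "number"
        },
        "mu": {
          "exclusiveMinimum": 0,
          "title": "Mu",
          "type": "number"
        },
        "beta": {
          "exclusiveMinimum": 0,
          "title": "Beta",
          "type": "number"
        },
        "alpha": {
          "exclusiveMinimum": 0,
          "title": "Alpha",
          "type": "number"
        },
        "gamma": {
          "exclusiveMinimum": 0,
          "title": "Gamma",
          "type": "number"
        },
        "epsilon": {
          "exclusiveMinimum": 0,
          "title": "Epsilon",
          "type": "number"
        },
        "sigma2": {
          "minimum": 0,
          "title": "Sigma2",
          "type": "number"
        }
      },
      "required": [
        "Lambda",
        "mu",
        "beta",
        "alpha",
        "gamma",
        "epsilon",
        "sigma2"
      ],
      "title": "RegimeConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Complete, serializable description of one experiment.",
  "properties": {
    "model": {
      "$ref": "#/$defs/ModelConfig"
    },
    "initial": {
      "$ref": "#/$defs/InitialConfig"
    },
    "numerics": {
      "$ref": "#/$defs/NumericsConfig",
      "default": {
        "T": 1000.0,
        "dt": 0.01,
        "n_paths": 200,
        "seed": 0,
        "extinction_floor": 0.0001,
        "hist_bins": 40,
        "hist_s_range": [
          0.0,
          3.5
        ],
        "hist_i_range": [
          0.0,
          3.5
        ],
        "window": null
      }
    },
    "outputs": {
      "$ref": "#/$defs/OutputsConfig",
      "default": {
        "trajectory_csv": null,
        "summary_json": null
      }
    },
    "label": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Label"
    },
    "notes": {
      "items": {
        "type": "string"
      },
      "title": "Notes",
      "type": "array"
    }
  },
  "required": [
    "model",
    "initial"
  ],
  "title": "ExperimentConfig",
  "type": "object"
}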