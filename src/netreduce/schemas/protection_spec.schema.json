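{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "netreduce protection specification",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "protected_metabolites": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Metabolite ids that must remain in the reduced network, each touched by at least one feasible reaction."
    },
    "protected_reactions": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Reaction ids that are never deleted and never lumped away."
    },
    "enforce_protected_feasibility": {
      "type": "boolean",
      "default": false,
      "description": "Require every protected reaction to be able to carry nonzero flux in at least one protected scenario."
    },
    "dof_min": {
      "type": "integer",
      "minimum": 0,
      "default": 1,
      "description": "Minimum degrees of freedom (n - rank(S)) of the reduced network."
    },
    "n_min": {
      "type": "integer",
      "minimum": 1,
      "default": 1,
      "description": "Minimum number of reactions in the reduced network."
    },
    "scenarios": {
      "type": "array",
      "description": "Protected functions/phenotypes; each must stay feasible.",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "bound_overrides": {
            "type": "object",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "number"},
              "minItems": 2,
              "maxItems": 2
            },
            "description": "Per-reaction [lower, upper] bounds applied only within this scenario."
          },
          "constraints": {
            "type": "array",
            "items": {"type": "string"},
            "description": "Linear inequality strings over reaction ids, e.g. 'R_glc_up <= 10' or '-mu <= -0.999 * FBA_MAX(mu)'. FBA_MAX(reaction) is resolved on the full model at load time."
          }
        }
      }
    }
  }
}
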