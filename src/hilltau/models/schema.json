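{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "HillTau model",
  "description": "A HillTau signaling model: species (boundary concentrations), reactions (Hill-form steady state + exponential relaxation) and algebraic equations. Reaction definition order is semantically meaningful (deterministic feedback breaking).",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "units": {
      "description": "Concentration unit for every concentration-typed value in the file. Default mM.",
      "enum": ["M", "mM", "uM", "nM"],
      "default": "mM"
    },
    "species": {
      "description": "Plain (non-computed) species; boundary conditions changed only by events/clamps. A bare number is shorthand for {\"concInit\": number}.",
      "type": "object",
      "additionalProperties": {
        "oneOf": [
          {"type": "number", "minimum": 0},
          {
            "type": "object",
            "additionalProperties": false,
            "properties": {
              "concInit": {"type": "number", "minimum": 0, "default": 0},
              "buffered": {"type": "boolean", "default": true}
            }
          }
        ]
      }
    },
    "reactions": {
      "description": "Map output-molecule name -> reaction. Output names must be disjoint from species and equation names.",
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": false,
        "required": ["input", "KA", "tau"],
        "properties": {
          "input": {"type": "string", "description": "Reagent Y_input; Yinf scales linearly with it."},
          "ligand": {"type": "string", "description": "Ligand L of the Hill term. Absent => conversion form Yinf = gain * Yinput^n / KA."},
          "modifier": {"type": "string", "description": "Modifier M rescaling the effective KA (requires Kmod; requires a ligand)."},
          "KA": {"type": "number", "exclusiveMinimum": 0, "description": "Association constant (concentration)."},
          "n": {"type": "number", "minimum": 0, "default": 1, "description": "Hill order of the ligand (real, >= 0)."},
          "tau": {"type": "number", "exclusiveMinimum": 0, "description": "Relaxation time constant, seconds (rising)."},
          "tau2": {"type": "number", "exclusiveMinimum": 0, "description": "Relaxation time constant when the output is falling. Default: tau."},
          "gain": {"type": "number", "exclusiveMinimum": 0, "default": 1, "description": "Output scale factor (enzymatic amplification)."},
          "baseline": {"type": "number", "minimum": 0, "default": 0, "description": "Additive baseline; the asymptote is Yinf + baseline."},
          "Kmod": {"type": "number", "exclusiveMinimum": 0, "description": "Half-effect concentration of the modifier. Required iff modifier present."},
          "Amod": {"type": "number", "exclusiveMinimum": 0, "default": 4, "description": "Modifier action: < 1 inhibitory, > 1 excitatory, 1 neutral."},
          "Nmod": {"type": "number", "minimum": 0, "default": 1, "description": "Order of the modifier action."},
          "inhibit": {"type": "boolean", "default": false, "description": "Ligand acts as an inhibitor: theta -> 1 - theta."},
          "concInit": {"type": "number", "minimum": 0, "description": "Explicit initial value for this output; default is the steady-state fallback Yinf + baseline at the initial upstream values."}
        }
      }
    },
    "equations": {
      "description": "Map output name -> algebraic expression over molecule names; whitelist grammar: numbers, names, + - * / **, unary minus, parentheses, exp/log/pow/min/max. Evaluated instantaneously (no tau).",
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "massaction": {
      "description": "Optional companion mass-action/Michaelis-Menten reference network (ODE oracle), ignored by the HillTau loader.",
      "type": "object"
    }
  }
}
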