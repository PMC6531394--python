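{
  "context": "human",
  "species": "human",
  "body_weight_kg": 70,
  "parameters": {
    "molecular_weight": {"value": 105, "unit": "kDa"},
    "kon_cd3": {"value": 1.72, "unit": "1/nM/h"},
    "koff_cd3": {"value": 19.66, "unit": "1/h"},
    "kon_pcad": {"value": 1.57, "unit": "1/nM/h"},
    "koff_pcad": {"value": 0.74, "unit": "1/h"},
    "kint": {"value": 0.1728, "unit": "1/day"},
    "v1": {"value": 40.2, "unit": "mL/kg"},
    "v2": {"value": 211, "unit": "mL/kg"},
    "cl": {"value": 4.61, "unit": "mL/h/kg"},
    "cld": {"value": 25.2, "unit": "mL/h/kg"},
    "permeability": {"value": 334, "unit": "um/day"},
    "diffusivity": {"value": 0.022, "unit": "cm^2/day"},
    "void_fraction": {"value": 0.24, "unit": "-"},
    "r_cap": {"value": 8, "unit": "um"},
    "r_krogh": {"value": 75, "unit": "um"},
    "r_tumor": {"value": 1.0, "unit": "cm"},
    "tumor_cell_density": {"value": 1e8, "unit": "cells/g"},
    "cd3_per_tcell": {"value": 100000, "unit": "receptors/cell"},
    "mpcad_per_tumor_cell": {"value": 28706, "unit": "receptors/cell"},
    "tcell_plasma_baseline": {"value": 5000, "unit": "cells/uL"},
    "tcell_tumor_density": {"value": 6.49e5, "unit": "cells/g"},
    "spcad_molecular_weight": {"value": 85, "unit": "kDa"},
    "spcad_baseline": {"value": 92.7, "unit": "ng/mL"},
    "kdeg": {"value": 0.15, "unit": "1/h"},
    "kdegcx": {"value": 0.115, "unit": "1/h"}
  },
  "extras": {
    "kdeg_monkey_per_h": 0.31,
    "allometric_exponents": {"clearance": 0.9, "volume": 1.0, "absorption": -0.25, "kdeg": -0.25}
  }
}
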