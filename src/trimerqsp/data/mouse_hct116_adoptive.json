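{
  "context": "hct116_adoptive",
  "species": "mouse",
  "body_weight_kg": 0.02,
  "parameters": {
    "molecular_weight": {"value": 105, "unit": "kDa"},
    "kon_cd3": {"value": 1.72, "unit": "1/nM/h"},
    "koff_cd3": {"value": 19.66, "unit": "1/h"},
    "kon_pcad": {"value": 1.57, "unit": "1/nM/h"},
    "koff_pcad": {"value": 0.74, "unit": "1/h"},
    "kint": {"value": 0.1728, "unit": "1/day"},
    "v1": {"value": 49.6, "unit": "mL/kg"},
    "v2": {"value": 60.7, "unit": "mL/kg"},
    "cl": {"value": 0.45, "unit": "mL/h/kg"},
    "cld": {"value": 4.95, "unit": "mL/h/kg"},
    "permeability": {"value": 334, "unit": "um/day"},
    "diffusivity": {"value": 0.022, "unit": "cm^2/day"},
    "void_fraction": {"value": 0.24, "unit": "-"},
    "r_cap": {"value": 8, "unit": "um"},
    "r_krogh": {"value": 75, "unit": "um"},
    "r_tumor": {"value": 0.5, "unit": "cm"},
    "tumor_cell_density": {"value": 1e8, "unit": "cells/g"},
    "cd3_per_tcell": {"value": 100000, "unit": "receptors/cell"},
    "mpcad_per_tumor_cell": {"value": 28706, "unit": "receptors/cell"},
    "tcells_administered": {"value": 5e6, "unit": "cells/animal"},
    "k_el_t": {"value": 2.51, "unit": "1/day"},
    "k_12_t": {"value": 0.002, "unit": "1/day"},
    "k_21_t": {"value": 0.0005, "unit": "1/day"},
    "t_lag": {"value": 5, "unit": "day"},
    "proliferation_window": {"value": 7, "unit": "day"},
    "k_exhaust": {"value": 0.0412, "unit": "1/h"},
    "kg0": {"value": 0.19, "unit": "1/day"},
    "kg": {"value": 123, "unit": "mm^3/day"},
    "m_max": {"value": 6000, "unit": "mm^3"},
    "psi": {"value": 20, "unit": "-"},
    "kmax": {"value": 1.32, "unit": "1/day"},
    "kc50": {"value": 6.9e-5, "unit": "nM"},
    "tau": {"value": 3.99, "unit": "day"}
  },
  "extras": {
    "tcell_timing": "adoptive",
    "tcell_time_days_relative_to_first_dose": 1,
    "cv_percent": {"kg0": 3, "kg": 2, "kmax": 7, "kc50": 7, "tau": 1,
                   "v1": 9, "v2": 16, "cl": 12, "cld": 28},
    "omega": {"kg0": 0.34, "kg": 0.16},
    "residual_error": {"a": 60, "b": 0.06},
    "reported_tsc_pM": 0.011,
    "reported_tsc_ci80_pM": [0.0096, 0.013]
  }
}
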