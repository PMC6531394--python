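"""Physical constants and species-level reference values.

Canonical internal units: time in hours, concentrations in nM, PK volumes
in mL/kg (converted to absolute litres only when a body weight enters),
tumor volumes in mm^3.
"""

# Avogadro's number at the 4-significant-figure convention used by the
# cell-surface-to-molar conversions throughout this model family.
AVOGADRO = 6.023e23

HOURS_PER_DAY = 24.0

# Reference body weights for cross-species (allometric) scaling.  The mouse
# blood/plasma reference volume converts cells administered per animal into
# a circulating concentration (5e6 cells/mouse <-> 2.5e9 cells/L).
MOUSE_BODY_WEIGHT_KG = 0.020
MOUSE_PLASMA_REFERENCE_L = 0.002
MONKEY_BODY_WEIGHT_KG = 3.5
HUMAN_BODY_WEIGHT_KG = 70.0

# Tumor tissue density: 1 g/mL, i.e. 1 mm^3 of tumor weighs 1 mg.  Used for
# cells/g <-> cells/L conversions and volume <-> radius geometry.
TUMOR_DENSITY_G_PER_ML = 1.0
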