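"""Typed parameter containers, unit conversions, and allometric scaling.

The model spans three unit systems that practitioners mix freely: mass-based
drug amounts (mg/kg doses, ng/mL assay readouts), molar concentrations (nM,
the ODE currency), and cell-surface receptor counts (receptors/cell times
cells/L).  Every conversion between them lives here, so the dynamical modules
can assume a single canonical system: hours, nM, mL/kg.

Rate constants tabulated per day (internalization, T-cell trafficking) are
stored as tabulated and exposed per hour through explicit ``*_per_hour``
properties; the ODE assemblies only ever read the hourly form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .constants import (
    AVOGADRO,
    HOURS_PER_DAY,
    MOUSE_PLASMA_REFERENCE_L,
)
from .errors import InvalidParameterError, SchemaError

__all__ = [
    "DrugProperties",
    "PKParameters",
    "TumorPhysiology",
    "CellularParameters",
    "SolubleTargetParameters",
    "TCellKineticParameters",
    "ParameterSet",
    "kd_from_rates",
    "cell_surface_to_molar",
    "mass_to_molar",
    "molar_to_mass",
    "dose_to_initial_concentration",
    "allometric_scale",
    "load_parameters",
    "bundled_contexts",
]


# ---------------------------------------------------------------------------
# scalar conversions


def kd_from_rates(koff: float, kon: float) -> float:
    """Equilibrium dissociation constant Kd = koff/kon.

    Parameters use the binding-kinetics convention: ``koff`` in 1/h,
    ``kon`` in 1/nM/h, so the result is in nM.
    """
    if kon <= 0:
        raise InvalidParameterError(f"kon must be positive, got {kon}")
    if koff < 0:
        raise InvalidParameterError(f"koff must be nonnegative, got {koff}")
    return koff / kon


def cell_surface_to_molar(cell_density: float, receptors_per_cell: float) -> float:
    """Convert a cell-surface receptor pool to a molar concentration (nM).

    ``cell_density`` in cells/L and ``receptors_per_cell`` as a count give
    receptors/L; dividing by Avogadro's number yields mol/L and the 1e9
    factor rescales to nmol/L.
    """
    if cell_density < 0 or receptors_per_cell < 0:
        raise InvalidParameterError("cell density and receptor count must be nonnegative")
    return (cell_density * receptors_per_cell / AVOGADRO) * 1e9


def mass_to_molar(conc_ng_per_ml: float, mw_kda: float) -> float:
    """ng/mL -> nM given a molecular weight in kDa.

    1 ng/mL = 1 ug/L and 1 kDa = 1 ug/nmol, so the ratio is already nmol/L.
    """
    if mw_kda <= 0:
        raise InvalidParameterError(f"molecular weight must be positive, got {mw_kda}")
    if conc_ng_per_ml < 0:
        raise InvalidParameterError("concentration must be nonnegative")
    return conc_ng_per_ml / mw_kda


def molar_to_mass(conc_nm: float, mw_kda: float) -> float:
    """nM -> ng/mL; inverse of :func:`mass_to_molar`."""
    if mw_kda <= 0:
        raise InvalidParameterError(f"molecular weight must be positive, got {mw_kda}")
    return conc_nm * mw_kda


def dose_to_initial_concentration(dose_mg_per_kg: float, mw_kda: float, v1_ml_per_kg: float) -> float:
    """Initial central-compartment concentration (nM) after an IV bolus.

    The dose in mg/kg is converted to nmol/kg (mg/kg divided by kDa equals
    umol/kg, i.e. 1000 nmol/kg) and divided by the central volume in L/kg.
    """
    if dose_mg_per_kg < 0:
        raise InvalidParameterError("dose must be nonnegative")
    if mw_kda <= 0:
        raise InvalidParameterError("molecular weight must be positive")
    if v1_ml_per_kg <= 0:
        raise InvalidParameterError("central volume must be positive")
    nmol_per_kg = dose_mg_per_kg / mw_kda * 1000.0
    return nmol_per_kg / (v1_ml_per_kg / 1000.0)


def allometric_scale(
    value: float,
    bw_source_kg: float,
    bw_target_kg: float,
    exponent: float,
    *,
    per_kg: bool = True,
) -> float:
    """Allometric interspecies scaling.

    For quantities already normalized per kg body weight (CL in mL/h/kg,
    V in mL/kg) the absolute quantity scales as BW**exponent, so the per-kg
    value picks up a factor (BW_target/BW_source)**(exponent - 1).  Pure
    rate constants (1/h) are not per-kg quantities; they scale directly as
    (BW_target/BW_source)**exponent (``per_kg=False``), which is how a
    first-order degradation rate with a -0.25 exponent is carried from
    monkey to human.
    """
    if bw_source_kg <= 0 or bw_target_kg <= 0:
        raise InvalidParameterError("body weights must be positive")
    ratio = bw_target_kg / bw_source_kg
    expo = exponent - 1.0 if per_kg else exponent
    return value * ratio**expo


# ---------------------------------------------------------------------------
# parameter containers


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite and positive, got {value}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0 or not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite and nonnegative, got {value}")


@dataclass(frozen=True)
class DrugProperties:
    """Binding kinetics and physical properties of the bispecific.

    molecular_weight : kDa
    kon_cd3, kon_pcad : 1/nM/h association rate constants
    koff_cd3, koff_pcad : 1/h dissociation rate constants
    kint : 1/day internalization rate of target-bound drug on tumor cells
    """

    molecular_weight: float
    kon_cd3: float
    koff_cd3: float
    kon_pcad: float
    koff_pcad: float
    kint: float

    def __post_init__(self) -> None:
        _require_positive(
            molecular_weight=self.molecular_weight,
            kon_cd3=self.kon_cd3,
            koff_cd3=self.koff_cd3,
            kon_pcad=self.kon_pcad,
            koff_pcad=self.koff_pcad,
        )
        _require_nonnegative(kint=self.kint)

    @property
    def kd_cd3(self) -> float:
        """CD3-arm equilibrium dissociation constant (nM)."""
        return kd_from_rates(self.koff_cd3, self.kon_cd3)

    @property
    def kd_pcad(self) -> float:
        """Tumor-antigen-arm equilibrium dissociation constant (nM)."""
        return kd_from_rates(self.koff_pcad, self.kon_pcad)

    @property
    def kint_per_hour(self) -> float:
        return self.kint / HOURS_PER_DAY


@dataclass(frozen=True)
class PKParameters:
    """Linear two-compartment disposition, per-kg parameterization.

    v1, v2 : mL/kg central and peripheral volumes
    cl, cld : mL/h/kg clearance and inter-compartmental clearance
    """

    v1: float
    v2: float
    cl: float
    cld: float

    def __post_init__(self) -> None:
        _require_positive(v1=self.v1, v2=self.v2, cl=self.cl, cld=self.cld)

    @property
    def kel(self) -> float:
        """Elimination rate constant CL/V1 (1/h)."""
        return self.cl / self.v1

    @property
    def k12(self) -> float:
        return self.cld / self.v1

    @property
    def k21(self) -> float:
        return self.cld / self.v2

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution V1 + V2 (mL/kg)."""
        return self.v1 + self.v2


@dataclass(frozen=True)
class TumorPhysiology:
    """Krogh-cylinder drug exchange and tumor composition.

    permeability : um/day across the capillary wall
    diffusivity : cm^2/day through tumor tissue
    void_fraction : accessible interstitial fraction (dimensionless)
    r_cap, r_krogh : um capillary radius and half inter-capillary distance
    r_tumor : cm tumor radius (may be recomputed from volume dynamically)
    tumor_cell_density : cells per g of tumor
    tissue_density : g/mL (1.0 -> 1 mm^3 weighs 1 mg)
    """

    permeability: float
    diffusivity: float
    void_fraction: float
    r_cap: float
    r_krogh: float
    r_tumor: float
    tumor_cell_density: float
    tissue_density: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            r_cap=self.r_cap,
            r_krogh=self.r_krogh,
            r_tumor=self.r_tumor,
            tissue_density=self.tissue_density,
        )
        # zero permeability/diffusivity decouples the tumor (no-exchange limit)
        _require_nonnegative(
            permeability=self.permeability,
            diffusivity=self.diffusivity,
            tumor_cell_density=self.tumor_cell_density,
        )
        if not 0 < self.void_fraction < 1:
            raise InvalidParameterError(
                f"void fraction must lie in (0, 1), got {self.void_fraction}"
            )


@dataclass(frozen=True)
class CellularParameters:
    """Receptor expression and cell-number context.

    cd3_per_tcell, mpcad_per_tumor_cell : receptors/cell
    tcell_plasma_baseline : cells/L in the central compartment (human) or
        the circulating concentration implied by cells administered per
        animal (mouse)
    tcell_tumor_density : cells per g of tumor at steady state (human only;
        None for mouse where tumor T cells are dynamic)
    """

    cd3_per_tcell: float
    mpcad_per_tumor_cell: float
    tcell_plasma_baseline: float
    tcell_tumor_density: float | None = None

    def __post_init__(self) -> None:
        _require_nonnegative(
            cd3_per_tcell=self.cd3_per_tcell,
            mpcad_per_tumor_cell=self.mpcad_per_tumor_cell,
            tcell_plasma_baseline=self.tcell_plasma_baseline,
        )
        if self.tcell_tumor_density is not None:
            _require_nonnegative(tcell_tumor_density=self.tcell_tumor_density)


@dataclass(frozen=True)
class SolubleTargetParameters:
    """Soluble (shed) target in the central compartment.

    spcad_baseline : nM pre-dose concentration
    kdeg : 1/h degradation rate of free soluble target
    kdegcx : 1/h degradation rate of the drug-target complex
    ksyn : nM/h zero-order synthesis; at homeostasis ksyn = kdeg * baseline
    """

    spcad_baseline: float
    kdeg: float
    kdegcx: float
    molecular_weight: float = 85.0

    def __post_init__(self) -> None:
        _require_nonnegative(spcad_baseline=self.spcad_baseline)
        _require_positive(kdeg=self.kdeg, kdegcx=self.kdegcx, molecular_weight=self.molecular_weight)

    @property
    def ksyn(self) -> float:
        """Synthesis rate pinned to baseline homeostasis (nM/h)."""
        return self.kdeg * self.spcad_baseline


@dataclass(frozen=True)
class TCellKineticParameters:
    """T-cell trafficking, proliferation window, and contraction (mouse).

    k_el_t, k_12_t, k_21_t : 1/day elimination and plasma<->tumor transfer
    t_lag : days between T-cell administration and their appearance in tumor
    proliferation_window : days of exponential expansion after the lag
    k_exhaust : 1/h mono-exponential contraction rate after the window
    """

    k_el_t: float
    k_12_t: float
    k_21_t: float
    t_lag: float = 5.0
    proliferation_window: float = 7.0
    k_exhaust: float = 0.0412

    def __post_init__(self) -> None:
        _require_nonnegative(
            k_el_t=self.k_el_t,
            k_12_t=self.k_12_t,
            k_21_t=self.k_21_t,
            t_lag=self.t_lag,
            proliferation_window=self.proliferation_window,
            k_exhaust=self.k_exhaust,
        )

    @property
    def k_el_t_per_hour(self) -> float:
        return self.k_el_t / HOURS_PER_DAY

    @property
    def k_12_t_per_hour(self) -> float:
        return self.k_12_t / HOURS_PER_DAY

    @property
    def k_21_t_per_hour(self) -> float:
        return self.k_21_t / HOURS_PER_DAY

    @property
    def t_lag_hours(self) -> float:
        return self.t_lag * HOURS_PER_DAY

    @property
    def window_hours(self) -> float:
        return self.proliferation_window * HOURS_PER_DAY


@dataclass(frozen=True)
class ParameterSet:
    """All drug/system/PK constants for one species context.

    ``growth`` holds the tumor growth/kill parameters for mouse contexts
    (see :mod:`trimerqsp.tgi`); ``soluble_target`` is present only for the
    human context; ``extras`` carries context metadata such as estimation
    CV%, inter-animal variability, and residual-error magnitudes.
    """

    context: str
    species: str
    body_weight_kg: float
    drug: DrugProperties
    pk: PKParameters
    tumor: TumorPhysiology
    cells: CellularParameters
    tcell_kinetics: TCellKineticParameters | None = None
    soluble_target: SolubleTargetParameters | None = None
    growth: "object | None" = None  # GrowthKillParameters; late-bound to avoid cycles
    extras: dict = field(default_factory=dict)

    def with_(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# parameter-file loading

# Units accepted in parameter files, mapped to a multiplier into the unit the
# containers store.  Keys are (field-group, unit-string).
_UNIT_TABLE = {
    ("rate_per_nM_h", "1/nM/h"): 1.0,
    ("rate_per_h", "1/h"): 1.0,
    ("rate_per_day", "1/day"): 1.0,
    ("mass_kda", "kDa"): 1.0,
    ("volume_ml_kg", "mL/kg"): 1.0,
    ("clearance", "mL/h/kg"): 1.0,
    ("length_um", "um"): 1.0,
    ("length_um", "μm"): 1.0,
    ("length_cm", "cm"): 1.0,
    ("perm_um_day", "um/day"): 1.0,
    ("perm_um_day", "μm/day"): 1.0,
    ("diff_cm2_day", "cm^2/day"): 1.0,
    ("dimensionless", "-"): 1.0,
    ("cells_per_g", "cells/g"): 1.0,
    ("cells_per_L", "cells/L"): 1.0,
    ("cells_per_uL", "cells/uL"): 1e6,  # -> cells/L
    ("receptors", "receptors/cell"): 1.0,
    ("conc_nM", "nM"): 1.0,
    ("conc_nM", "ng/mL"): None,  # needs molecular weight; handled specially
    ("density_g_ml", "g/mL"): 1.0,
    ("time_day", "day"): 1.0,
    ("cells_per_animal", "cells/animal"): 1.0,
}


def _get(entry_map: dict, key: str, group: str, mw: float | None = None) -> float:
    try:
        entry = entry_map[key]
    except KeyError as exc:
        raise SchemaError(f"parameter file is missing entry '{key}'") from exc
    if not isinstance(entry, dict) or "value" not in entry or "unit" not in entry:
        raise SchemaError(f"entry '{key}' must be an object with 'value' and 'unit'")
    unit = entry["unit"]
    value = float(entry["value"])
    if (group, unit) not in _UNIT_TABLE:
        raise SchemaError(f"entry '{key}': unit '{unit}' not valid for {group}")
    factor = _UNIT_TABLE[(group, unit)]
    if factor is None:  # ng/mL -> nM via molecular weight
        if mw is None:
            raise SchemaError(f"entry '{key}': ng/mL requires a molecular weight")
        return mass_to_molar(value, mw)
    return value * factor


_BUNDLED = {
    "hct116_engrafted": "mouse_hct116_engrafted.json",
    "hct116_adoptive": "mouse_hct116_adoptive.json",
    "sum149_adoptive": "mouse_sum149_adoptive.json",
    "human": "human.json",
}


def bundled_contexts() -> list[str]:
    """Names of parameter contexts shipped with the package."""
    return sorted(_BUNDLED)


def load_parameters(source: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a bundled context name or JSON path.

    Files carry explicit unit strings per entry; units are validated and
    converted to the containers' canonical units on load.
    """
    from .tgi import GrowthKillParameters  # deferred: tgi imports nothing from here

    if isinstance(source, str) and source in _BUNDLED:
        text = (resources.files("trimerqsp.data") / _BUNDLED[source]).read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise SchemaError(f"parameter file not found: {source}")
        text = path.read_text()
    raw = json.loads(text)

    p = raw.get("parameters", {})
    species = raw.get("species")
    if species not in {"mouse", "human"}:
        raise SchemaError(f"species must be 'mouse' or 'human', got {species!r}")

    mw = _get(p, "molecular_weight", "mass_kda")
    drug = DrugProperties(
        molecular_weight=mw,
        kon_cd3=_get(p, "kon_cd3", "rate_per_nM_h"),
        koff_cd3=_get(p, "koff_cd3", "rate_per_h"),
        kon_pcad=_get(p, "kon_pcad", "rate_per_nM_h"),
        koff_pcad=_get(p, "koff_pcad", "rate_per_h"),
        kint=_get(p, "kint", "rate_per_day"),
    )
    pk = PKParameters(
        v1=_get(p, "v1", "volume_ml_kg"),
        v2=_get(p, "v2", "volume_ml_kg"),
        cl=_get(p, "cl", "clearance"),
        cld=_get(p, "cld", "clearance"),
    )
    tumor = TumorPhysiology(
        permeability=_get(p, "permeability", "perm_um_day"),
        diffusivity=_get(p, "diffusivity", "diff_cm2_day"),
        void_fraction=_get(p, "void_fraction", "dimensionless"),
        r_cap=_get(p, "r_cap", "length_um"),
        r_krogh=_get(p, "r_krogh", "length_um"),
        r_tumor=_get(p, "r_tumor", "length_cm"),
        tumor_cell_density=_get(p, "tumor_cell_density", "cells_per_g"),
    )

    if species == "mouse":
        tcells_per_animal = _get(p, "tcells_administered", "cells_per_animal")
        baseline = tcells_per_animal / MOUSE_PLASMA_REFERENCE_L
        tumor_density = None
    else:
        baseline = _get(p, "tcell_plasma_baseline", "cells_per_uL")
        tumor_density = _get(p, "tcell_tumor_density", "cells_per_g")
    cells = CellularParameters(
        cd3_per_tcell=_get(p, "cd3_per_tcell", "receptors"),
        mpcad_per_tumor_cell=_get(p, "mpcad_per_tumor_cell", "receptors"),
        tcell_plasma_baseline=baseline,
        tcell_tumor_density=tumor_density,
    )

    tck = None
    if "k_el_t" in p:
        tck = TCellKineticParameters(
            k_el_t=_get(p, "k_el_t", "rate_per_day"),
            k_12_t=_get(p, "k_12_t", "rate_per_day"),
            k_21_t=_get(p, "k_21_t", "rate_per_day"),
            t_lag=_get(p, "t_lag", "time_day"),
            proliferation_window=_get(p, "proliferation_window", "time_day"),
            k_exhaust=_get(p, "k_exhaust", "rate_per_h"),
        )

    soluble = None
    if "spcad_baseline" in p:
        spcad_mw = _get(p, "spcad_molecular_weight", "mass_kda")
        soluble = SolubleTargetParameters(
            spcad_baseline=_get(p, "spcad_baseline", "conc_nM", mw=spcad_mw),
            kdeg=_get(p, "kdeg", "rate_per_h"),
            kdegcx=_get(p, "kdegcx", "rate_per_h"),
            molecular_weight=spcad_mw,
        )

    growth = None
    if "kg0" in p:
        growth = GrowthKillParameters(
            kg0=_get(p, "kg0", "rate_per_day"),
            kg=float(p["kg"]["value"]),  # mm^3/day
            m_max=float(p["m_max"]["value"]),  # mm^3
            psi=float(p.get("psi", {"value": 20.0})["value"]),
            kmax=_get(p, "kmax", "rate_per_day"),
            kc50=_get(p, "kc50", "conc_nM"),
            tau=_get(p, "tau", "time_day"),
        )

    return ParameterSet(
        context=raw.get("context", str(source)),
        species=species,
        body_weight_kg=float(raw["body_weight_kg"]),
        drug=drug,
        pk=pk,
        tumor=tumor,
        cells=cells,
        tcell_kinetics=tck,
        soluble_target=soluble,
        growth=growth,
        extras=raw.get("extras", {}),
    )
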