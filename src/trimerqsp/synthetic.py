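"""Synthetic xenograft-study generators.

Emulates the three data streams the fitting module consumes, with the
statistical structure typical of such studies: tumor-volume trajectories
with log-normal inter-animal variability on the growth rates and combined
additive + proportional residual error; destructively-sampled serum/tumor
PK observations with assay lower limits; and tumor-infiltrating-lymphocyte
(TIL) counts following the dose-dependent expansion kinetics.

All generators are pure functions of (design, seed).  Each generator owns a
named pseudo-random substream so adding one does not perturb the draws of
another at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HOURS_PER_DAY
from .datasets import Dataset
from .errors import InvalidParameterError
from .fitting import make_trimer_driver
from .mouse import MouseScenario, prate_from_dose, simulate_mouse
from .parameters import ParameterSet
from .tgi import GrowthKillParameters, simulate_tgi

__all__ = ["StudyDesign", "generate_tgi_dataset", "generate_pk_dataset", "generate_til_dataset"]

# substream tags (any fixed distinct integers)
_STREAM_TGI = 101
_STREAM_PK = 202
_STREAM_TIL = 303

SERUM_LLOQ_NG_ML = 12.5
TUMOR_LLOQ_NG_ML = 1.5


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic xenograft study.

    arms : dose levels in mg/kg, 0 = vehicle
    n_per_arm : animals per arm
    obs_times_day : tumor-volume measurement schedule (twice weekly typical)
    truth : mouse :class:`ParameterSet` whose ``growth`` and ``extras``
        (omegas, residual error) are the generating values
    seed : mandatory; all randomness derives from it
    """

    truth: ParameterSet
    seed: int
    arms: tuple = (0.0, 0.05, 0.5)
    n_per_arm: int = 10
    obs_times_day: tuple = tuple(np.arange(0.0, 63.1, 3.5))
    dose_times_h: tuple = (0.0, 168.0)
    tcells_per_animal: float = 5e6
    tcell_time_h: float = 24.0
    initial_volume_mm3: float = 150.0
    initial_volume_sdlog: float = 0.2
    caliper_limit_mm3: float = 10.0
    volume_cap_mm3: float = 3500.0
    pk_times_h: tuple = (0.083, 1, 6, 24, 48, 96, 168, 240)
    til_times_h: tuple = (0.0, 24.0, 72.0, 144.0)
    til_baseline_per_mg: float = 1000.0
    til_sdlog: float = 0.3
    pk_n_per_point: int = 3
    til_n_per_point: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidParameterError("a seed is mandatory")
        if self.n_per_arm < 1:
            raise InvalidParameterError("n_per_arm must be >= 1")
        if self.truth.growth is None:
            raise InvalidParameterError("truth ParameterSet must carry growth parameters")

    def scenario(self, dose_mg_per_kg: float) -> MouseScenario:
        return MouseScenario(
            dose_mg_per_kg=dose_mg_per_kg,
            dose_times_h=self.dose_times_h,
            tcells_per_animal=self.tcells_per_animal,
            tcell_time_h=self.tcell_time_h,
            initial_tumor_volume_mm3=self.initial_volume_mm3,
        )


def _rows(records: list[dict]) -> Dataset:
    return Dataset(pd.DataFrame.from_records(records))


def generate_tgi_dataset(design: StudyDesign) -> Dataset:
    """Tumor-volume study: per-animal growth variability + measurement noise.

    Per animal, kg0 and kg are drawn log-normally around the truth medians
    (sdlog = omega), the initial volume is drawn log-normally, the TGI chain
    is integrated against the arm's trimer exposure, and combined
    additive + proportional noise is added at the scheduled times.  Values
    at or below the caliper limit are reported at the limit and flagged
    censored; animals are truncated (euthanasia) once the noise-free volume
    exceeds the cap.
    """
    rng = np.random.default_rng([_STREAM_TGI, design.seed])
    gk_true: GrowthKillParameters = design.truth.growth
    extras = design.truth.extras
    omega_kg0 = float(extras.get("omega", {}).get("kg0", 0.0))
    omega_kg = float(extras.get("omega", {}).get("kg", 0.0))
    err = extras.get("residual_error", {"a": 0.0, "b": 0.0})
    a_err, b_err = float(err["a"]), float(err["b"])

    t_days = np.asarray(design.obs_times_day, dtype=float)
    t_end_h = float(t_days[-1]) * HOURS_PER_DAY + 24.0

    records: list[dict] = []
    realized: list[dict] = []
    for dose in design.arms:
        if dose > 0:
            driver = make_trimer_driver(design.scenario(dose), design.truth, t_end_h)
        else:
            driver = lambda t: 0.0  # noqa: E731 - vehicle arm has no exposure
        for i in range(design.n_per_arm):
            animal = f"d{dose:g}_a{i:02d}"
            kg0_i = gk_true.kg0 * np.exp(rng.normal(0.0, omega_kg0)) if omega_kg0 else gk_true.kg0
            kg_i = gk_true.kg * np.exp(rng.normal(0.0, omega_kg)) if omega_kg else gk_true.kg
            w0_i = design.initial_volume_mm3 * (
                np.exp(rng.normal(0.0, design.initial_volume_sdlog))
                if design.initial_volume_sdlog else 1.0
            )
            gk_i = GrowthKillParameters(
                kg0=kg0_i, kg=kg_i, m_max=gk_true.m_max, psi=gk_true.psi,
                kmax=gk_true.kmax, kc50=gk_true.kc50, tau=gk_true.tau,
            )
            realized.append({"id": animal, "dose": dose, "kg0": kg0_i, "kg": kg_i, "w0": w0_i})
            w = simulate_tgi(driver, gk_i, w0_i, t_days, rtol=1e-7, atol=1e-7)[:, 4]
            alive = np.cumprod(w <= design.volume_cap_mm3).astype(bool)
            alive[0] = True
            noise = rng.normal(0.0, 1.0, size=len(t_days))
            for t, vol, keep, z in zip(t_days, w, alive, noise):
                if not keep:
                    break
                obs = vol + z * np.sqrt(a_err**2 + (b_err * vol) ** 2)
                censored = obs <= design.caliper_limit_mm3
                records.append({
                    "id": animal, "group": f"{dose:g} mg/kg", "dose": dose,
                    "dose_unit": "mg/kg", "time": t, "time_unit": "day",
                    "obs": design.caliper_limit_mm3 if censored else obs,
                    "obs_type": "tumor_volume", "censored": censored,
                })
    ds = _rows(records)
    ds.realized = pd.DataFrame.from_records(realized)
    return ds


def generate_pk_dataset(design: StudyDesign, proportional_sd: float = 0.10,
                        additive_sd_ng_ml: float = 1.0) -> Dataset:
    """Destructive-sampling PK study: serum and tumor drug concentrations.

    Independent animals at each time point (terminal sampling); observations
    below the assay lower limits are reported at the limit and flagged
    censored, never dropped.
    """
    rng = np.random.default_rng([_STREAM_PK, design.seed])
    times_h = np.asarray(design.pk_times_h, dtype=float)
    records: list[dict] = []
    for dose in design.arms:
        if dose <= 0:
            continue
        scen = MouseScenario(
            dose_mg_per_kg=dose, dose_times_h=(0.0,),
            tcells_per_animal=design.tcells_per_animal,
            tcell_time_h=design.tcell_time_h,
            initial_tumor_volume_mm3=design.initial_volume_mm3,
        )
        df = simulate_mouse(
            scen, design.truth, t_end_h=times_h[-1] + 1.0, n_points=400, dynamic_tv=False
        )
        mw = design.truth.drug.molecular_weight
        serum = np.interp(times_h, df["time_h"], df["serum_total_ng_ml"])
        tumor_total_nM = (df["c3"] + df["dcd3t"] + df["dpcadt"] + df["trimer"]).to_numpy()
        tumor = np.interp(times_h, df["time_h"], tumor_total_nM) * mw
        for t, s_true, tu_true in zip(times_h, serum, tumor):
            for j in range(design.pk_n_per_point):
                animal = f"pk_d{dose:g}_t{t:g}_a{j}"
                for obs_type, true_val, lloq in (
                    ("serum_conc", s_true, SERUM_LLOQ_NG_ML),
                    ("tumor_conc", tu_true, TUMOR_LLOQ_NG_ML),
                ):
                    val = true_val + rng.normal(0.0, np.sqrt(
                        additive_sd_ng_ml**2 + (proportional_sd * true_val) ** 2))
                    censored = val < lloq
                    records.append({
                        "id": animal, "group": f"{dose:g} mg/kg", "dose": dose,
                        "dose_unit": "mg/kg", "time": t, "time_unit": "h",
                        "obs": lloq if censored else val,
                        "obs_type": obs_type, "censored": censored,
                    })
    return _rows(records)


def generate_til_dataset(design: StudyDesign) -> Dataset:
    """Tumor-infiltrating CD3+ counts (cells/mg) at a few terminal times.

    Noise-free counts follow the dose-dependent exponential expansion, so a
    log-linear regression over the proliferation window recovers the
    proliferation rate by construction; log-normal noise is applied.
    """
    rng = np.random.default_rng([_STREAM_TIL, design.seed])
    times_h = np.asarray(design.til_times_h, dtype=float)
    records: list[dict] = []
    for dose in design.arms:
        prate = prate_from_dose(dose * 1000.0)
        for t in times_h:
            true_val = design.til_baseline_per_mg * np.exp(prate * t)
            for j in range(design.til_n_per_point):
                animal = f"til_d{dose:g}_t{t:g}_a{j}"
                val = true_val * (
                    np.exp(rng.normal(0.0, design.til_sdlog)) if design.til_sdlog else 1.0
                )
                records.append({
                    "id": animal, "group": f"{dose:g} mg/kg", "dose": dose,
                    "dose_unit": "mg/kg", "time": t, "time_unit": "h",
                    "obs": val, "obs_type": "til_count", "censored": False,
                })
    return _rows(records)
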