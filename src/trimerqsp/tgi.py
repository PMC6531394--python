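"""Tumor growth inhibition transduction model and tumor-static concentration.

Unperturbed growth follows a switched logistic law: near-exponential at rate
``kg0`` while the tumor is small, crossing sharply (switch constant ``psi``)
to linear growth at rate ``kg`` and saturating at carrying capacity
``m_max``.  Trimer-driven kill removes cells from the proliferating
compartment M1 at a saturable rate and pushes them through a three-stage
transduction (transit) chain with time constant ``tau`` before the volume is
actually lost, reproducing the delay between exposure and shrinkage.

The tumor-static concentration (TSC) is the trimer level at which kill
exactly balances exponential growth:

    TSC = kg0 * kc50 / (kmax - kg0)

All rates in this module are per day; tumor volumes in mm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, NumericalError, StasisUnreachableError

__all__ = [
    "GrowthKillParameters",
    "TGIState",
    "kill_rate",
    "growth_rate",
    "tgi_rhs",
    "simulate_tgi",
    "tsc",
    "tsc_confidence_interval",
    "combined_ceff",
]


@dataclass(frozen=True)
class GrowthKillParameters:
    """Growth and drug-effect parameters of the TGI model.

    kg0 : 1/day exponential growth rate
    kg : mm^3/day linear growth rate
    m_max : mm^3 carrying capacity
    psi : dimensionless switch sharpness (fixed at 20)
    kmax : 1/day maximum kill rate
    kc50 : nM trimer concentration at half-maximal kill
    tau : day transduction time constant
    """

    kg0: float
    kg: float
    m_max: float
    psi: float
    kmax: float
    kc50: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("kg0", "kg", "m_max", "kmax", "kc50", "tau"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if self.psi < 1:
            raise InvalidParameterError(f"psi must be >= 1, got {self.psi}")


@dataclass
class TGIState:
    """Tumor volume split across the growth and transduction compartments."""

    m1: float
    m2: float
    m3: float
    m4: float

    @property
    def w(self) -> float:
        """Total measurable tumor volume (mm^3)."""
        return self.m1 + self.m2 + self.m3 + self.m4


def kill_rate(trimer: float, kmax: float, kc50: float) -> float:
    """Saturable (Hill-1) kill rate (1/day) as a function of trimer (nM)."""
    if trimer < 0:
        raise InvalidParameterError(f"trimer must be nonnegative, got {trimer}")
    return kmax * trimer / (kc50 + trimer)


def growth_rate(w: float, gk: GrowthKillParameters) -> float:
    """Per-volume growth rate (1/day) of the switched logistic law at size w."""
    cap = 1.0 - w / gk.m_max
    switch = (1.0 + (gk.kg0 / gk.kg * w) ** gk.psi) ** (1.0 / gk.psi)
    return gk.kg0 * cap / switch


def tgi_rhs(m: np.ndarray, trimer: float, gk: GrowthKillParameters) -> np.ndarray:
    """Derivatives (per day) of [m1, m2, m3, m4] at trimer exposure (nM)."""
    m1, m2, m3, m4 = m
    w = m1 + m2 + m3 + m4
    kk = kill_rate(max(trimer, 0.0), gk.kmax, gk.kc50)
    dm1 = growth_rate(w, gk) * m1 - kk * m1
    dm2 = kk * m1 - m2 / gk.tau
    dm3 = (m2 - m3) / gk.tau
    dm4 = (m3 - m4) / gk.tau
    return np.array([dm1, dm2, dm3, dm4])


def simulate_tgi(
    trimer_fn,
    gk: GrowthKillParameters,
    w0: float,
    t_days: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the TGI chain driven by a trimer time course.

    ``trimer_fn`` maps time in days to trimer concentration in nM.  The
    initial volume starts entirely in the growth compartment.  Returns an
    array of shape (len(t_days), 5): columns m1..m4 and w.
    """
    t_days = np.asarray(t_days, dtype=float)
    t0, t1 = float(t_days[0]), float(t_days[-1])

    def rhs(t, m):
        return tgi_rhs(m, float(trimer_fn(t)), gk)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        [w0, 0.0, 0.0, 0.0],
        t_eval=t_days,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"TGI integration failed: {sol.message}")
    m = sol.y.T
    return np.column_stack([m, m.sum(axis=1)])


def tsc(kg0: float, kmax: float, kc50: float) -> float:
    """Tumor-static trimer concentration (same units as kc50).

    Setting kill equal to exponential growth, kmax*T/(kc50+T) = kg0, gives
    T = kg0*kc50/(kmax - kg0).  Requires kmax > kg0; otherwise even a
    saturating trimer exposure cannot hold the tumor static.
    """
    if kg0 < 0 or kc50 <= 0:
        raise InvalidParameterError("kg0 must be >= 0 and kc50 > 0")
    if kmax <= kg0:
        raise StasisUnreachableError(
            f"kmax ({kmax}) must exceed kg0 ({kg0}) for a finite TSC"
        )
    return kg0 * kc50 / (kmax - kg0)


def tsc_confidence_interval(
    estimates: dict,
    cv_percents: dict,
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.80,
) -> dict:
    """Parametric-bootstrap confidence interval on the TSC.

    ``estimates`` holds the point estimates of kg0, kmax and kc50 and
    ``cv_percents`` their estimation CVs in percent.  Each bootstrap draw
    resamples the three parameters independently from log-normal
    distributions whose median equals the point estimate, with
    sdlog = sqrt(ln(1 + CV^2)).  Draws with kmax <= kg0 yield no finite TSC
    and are discarded but counted.  Returns the point TSC, the percentile
    interval and the discarded fraction, all in the units of kc50.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required for a reproducible bootstrap")
    if n_boot < 100:
        raise InvalidParameterError("n_boot must be at least 100")
    for name in ("kg0", "kmax", "kc50"):
        if name not in estimates:
            raise InvalidParameterError(f"estimates must include {name}")
        if cv_percents.get(name, 0.0) < 0:
            raise InvalidParameterError(f"CV for {name} must be nonnegative")

    rng = np.random.default_rng(seed)
    draws = {}
    for name in ("kg0", "kmax", "kc50"):
        median = estimates[name]
        cv = cv_percents.get(name, 0.0) / 100.0
        sdlog = math.sqrt(math.log1p(cv * cv))
        if sdlog == 0.0:
            draws[name] = np.full(n_boot, median)
        else:
            draws[name] = median * np.exp(rng.normal(0.0, sdlog, size=n_boot))

    valid = draws["kmax"] > draws["kg0"]
    n_discarded = int(n_boot - valid.sum())
    tscs = (
        draws["kg0"][valid] * draws["kc50"][valid] / (draws["kmax"][valid] - draws["kg0"][valid])
    )
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(tscs, [alpha, 1.0 - alpha])
    result = {
        "tsc": tsc(estimates["kg0"], estimates["kmax"], estimates["kc50"]),
        "lower": float(lower),
        "upper": float(upper),
        "level": level,
        "n_boot": n_boot,
        "n_discarded": n_discarded,
        "discarded_fraction": n_discarded / n_boot,
        "seed": seed,
    }
    if result["discarded_fraction"] > 0.10:
        result["warning"] = (
            f"{result['discarded_fraction']:.1%} of bootstrap draws had kmax <= kg0 "
            "and were discarded; the interval may be unreliable"
        )
    return result


def combined_ceff(tsc_values) -> dict:
    """Combine per-model TSCs into a single efficacious-concentration value.

    Returns both the arithmetic and the geometric mean, explicitly labelled:
    conventions differ in the field and the two can disagree substantially,
    so neither is silently preferred.  Units follow the inputs.
    """
    values = np.asarray(list(tsc_values), dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise InvalidParameterError("TSC values must be positive and nonempty")
    return {
        "arithmetic_mean": float(values.mean()),
        "geometric_mean": float(np.exp(np.log(values).mean())),
        "n_models": int(values.size),
    }
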