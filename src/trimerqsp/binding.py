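"""Tumor-compartment binding kinetics shared by the mouse and human models.

The drug enters the tumor interstitium by a Krogh-cylinder exchange flux and
there binds CD3 on T cells and the membrane antigen on tumor cells by mass
action, forming two inactive dimers and the cytotoxic trimer.  Free-receptor
pools are expressed per interstitial volume, i.e. the total receptor
concentration minus bound species is divided by the void fraction ``eps``
inside the association terms; the complex concentrations themselves are not
rescaled.  That bookkeeping is kept exactly as the model family writes it.

Internalization removes only the antigen dimer (rate ``kint``); the trimer
is lost solely by dissociation.

``equilibrium_solve`` is an independent algebraic solution of the same
binding scheme at equilibrium (``kint = 0``), used as an oracle against the
kinetic right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import IntegrityError, InvalidParameterError, NumericalError
from .parameters import DrugProperties, TumorPhysiology

__all__ = [
    "TumorBindingState",
    "uptake_rate_constant",
    "disposition_flux",
    "binding_rhs",
    "equilibrium_solve",
]

_CAP_TOL = 1e-9  # nM slack allowed on receptor caps before declaring failure


@dataclass
class TumorBindingState:
    """Concentrations (nM) of the drug species in the tumor interstitium.

    ``tot_cd3_t`` and ``tot_pcad_t`` are the total receptor pools; the free
    pools are the totals minus the corresponding dimer and the trimer.
    """

    c3: float
    dcd3t: float
    dpcadt: float
    trimer: float
    tot_cd3_t: float
    tot_pcad_t: float

    def validate(self, tol: float = _CAP_TOL) -> None:
        for name in ("c3", "dcd3t", "dpcadt", "trimer", "tot_cd3_t", "tot_pcad_t"):
            if getattr(self, name) < -tol:
                raise IntegrityError(f"{name} is negative beyond tolerance: {getattr(self, name)}")
        if self.dcd3t + self.trimer > self.tot_cd3_t + tol:
            raise IntegrityError("CD3 receptor cap violated")
        if self.dpcadt + self.trimer > self.tot_pcad_t + tol:
            raise IntegrityError("tumor-antigen receptor cap violated")


def uptake_rate_constant(phys: TumorPhysiology, r_tumor_cm: float | None = None) -> float:
    """Krogh-cylinder tumor uptake rate constant (1/day).

    Sum of a trans-capillary surface term, 2*P*Rcap/Rkrogh^2, and a radial
    diffusion term, 6*D/Rtumor^2.  ``r_tumor_cm`` overrides the physiology's
    static radius when the tumor volume is dynamic.
    """
    r_tumor = phys.r_tumor if r_tumor_cm is None else r_tumor_cm
    if r_tumor <= 0:
        raise InvalidParameterError(f"tumor radius must be positive, got {r_tumor}")
    # permeability um/day over um^2 -> 1/day; diffusivity cm^2/day over cm^2 -> 1/day
    surface = 2.0 * phys.permeability * phys.r_cap / phys.r_krogh**2
    diffusion = 6.0 * phys.diffusivity / r_tumor**2
    return surface + diffusion


def disposition_flux(
    c1: float, c3: float, phys: TumorPhysiology, r_tumor_cm: float | None = None
) -> float:
    """Drug exchange flux between plasma and tumor interstitium (nM/day).

    Positive values move drug into the tumor; the gradient is taken against
    the interstitial free concentration ``c3/eps``.
    """
    return uptake_rate_constant(phys, r_tumor_cm) * (c1 - c3 / phys.void_fraction)


def binding_rhs(
    state: TumorBindingState,
    drug: DrugProperties,
    eps: float,
    disposition: float = 0.0,
    kint_per_h: float | None = None,
) -> tuple[float, float, float, float]:
    """Time derivatives (nM/h) of (c3, dcd3t, dpcadt, trimer).

    ``disposition`` is the plasma-tumor exchange flux in nM/h (already
    converted by the caller); ``kint_per_h`` defaults to the drug's
    internalization rate.
    """
    if not 0 < eps <= 1:
        raise InvalidParameterError(f"void fraction must be in (0, 1], got {eps}")
    if kint_per_h is None:
        kint_per_h = drug.kint_per_hour

    free_cd3 = (state.tot_cd3_t - state.dcd3t - state.trimer) / eps
    free_pcad = (state.tot_pcad_t - state.dpcadt - state.trimer) / eps

    c3, dcd3t, dpcadt, trimer = state.c3, state.dcd3t, state.dpcadt, state.trimer
    kon_c, koff_c = drug.kon_cd3, drug.koff_cd3
    kon_p, koff_p = drug.kon_pcad, drug.koff_pcad

    dc3 = (
        disposition
        - kon_p * c3 * free_pcad
        + koff_p * dpcadt
        - kon_c * c3 * free_cd3
        + koff_c * dcd3t
    )
    ddcd3t = (
        kon_c * c3 * free_cd3
        - koff_c * dcd3t
        - kon_p * dcd3t * free_pcad
        + koff_p * trimer
    )
    ddpcadt = (
        kon_p * c3 * free_pcad
        - koff_p * dpcadt
        - kon_c * dpcadt * free_cd3
        + koff_c * trimer
        - kint_per_h * dpcadt
    )
    dtrimer = (
        kon_c * dpcadt * free_cd3
        - koff_c * trimer
        + kon_p * dcd3t * free_pcad
        - koff_p * trimer
    )
    return dc3, ddcd3t, ddpcadt, dtrimer


def equilibrium_solve(
    c3_free: float,
    tot_cd3_t: float,
    tot_pcad_t: float,
    drug: DrugProperties,
    eps: float = 1.0,
) -> TumorBindingState:
    """Algebraic equilibrium of the binding scheme at fixed free drug.

    With ``kint = 0`` and no disposition, detailed balance fixes the dimers
    and trimer in terms of the free (per-interstitium) receptor pools
    x = freeCD3 and y = freePcad:

        DCD3t  = C3 * x / Kd_CD3
        DPcadt = C3 * y / Kd_Pcad
        Trimer = C3 * x * y / (Kd_CD3 * Kd_Pcad)

    Substituting into the CD3 conservation law makes x a linear function of
    y, leaving a single monotone scalar equation in y solved by bracketing.
    The returned state zeroes :func:`binding_rhs` (kint = 0) to solver
    tolerance.
    """
    if c3_free < 0 or tot_cd3_t < 0 or tot_pcad_t < 0:
        raise InvalidParameterError("concentrations must be nonnegative")
    if not 0 < eps <= 1:
        raise InvalidParameterError(f"void fraction must be in (0, 1], got {eps}")

    kd_c = drug.kd_cd3
    kd_p = drug.kd_pcad
    c = c3_free

    if c == 0 or (tot_cd3_t == 0 and tot_pcad_t == 0):
        return TumorBindingState(c, 0.0, 0.0, 0.0, tot_cd3_t, tot_pcad_t)

    def x_of_y(y: float) -> float:
        # TotCD3 = eps*x + C*x/KdC + C*x*y/(KdC*KdP)  ->  linear in x
        return tot_cd3_t / (eps + c / kd_c + c * y / (kd_c * kd_p))

    def pcad_residual(y: float) -> float:
        x = x_of_y(y)
        return eps * y + c * y / kd_p + c * x * y / (kd_c * kd_p) - tot_pcad_t

    y_hi = tot_pcad_t / eps
    if pcad_residual(y_hi) < 0:
        raise NumericalError("equilibrium bracketing failed: residual negative at upper bound")
    try:
        y = brentq(pcad_residual, 0.0, y_hi, xtol=1e-16, rtol=8.9e-16, maxiter=300)
    except (ValueError, RuntimeError) as exc:
        raise NumericalError(
            f"equilibrium solve failed (c3={c}, totCD3={tot_cd3_t}, totPcad={tot_pcad_t}): {exc}"
        ) from exc
    x = x_of_y(y)
    dcd3t = c * x / kd_c
    dpcadt = c * y / kd_p
    trimer = c * x * y / (kd_c * kd_p)
    state = TumorBindingState(c, dcd3t, dpcadt, trimer, tot_cd3_t, tot_pcad_t)
    state.validate(tol=1e-7 * max(1.0, tot_cd3_t, tot_pcad_t))
    return state
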