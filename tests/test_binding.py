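"""Tumor-compartment binding kinetics and the equilibrium oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trimerqsp import (
    DrugProperties,
    TumorBindingState,
    binding_rhs,
    disposition_flux,
    equilibrium_solve,
    uptake_rate_constant,
)
from trimerqsp.errors import InvalidParameterError
from trimerqsp.parameters import TumorPhysiology


def _phys(r_tumor=1.0, **kwargs):
    defaults = dict(permeability=334.0, diffusivity=0.022, void_fraction=0.24,
                    r_cap=8.0, r_krogh=75.0, r_tumor=r_tumor, tumor_cell_density=1e8)
    defaults.update(kwargs)
    return TumorPhysiology(**defaults)


def _drug(**kwargs):
    defaults = dict(molecular_weight=105.0, kon_cd3=1.72, koff_cd3=19.66,
                    kon_pcad=1.57, koff_pcad=0.74, kint=0.1728)
    defaults.update(kwargs)
    return DrugProperties(**defaults)


class TestUptakeRate:
    def test_reference_tumor(self):
        """Surface and diffusion terms for the 1-cm reference tumor."""
        k = uptake_rate_constant(_phys())
        assert k == pytest.approx(0.950 + 0.132, rel=5e-3)

    def test_no_exchange_limit(self):
        assert uptake_rate_constant(_phys(permeability=0.0, diffusivity=0.0)) == 0.0

    def test_large_tumor_keeps_surface_term(self):
        k = uptake_rate_constant(_phys(), r_tumor_cm=1e6)
        assert k == pytest.approx(0.950, rel=5e-3)

    def test_zero_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            uptake_rate_constant(_phys(), r_tumor_cm=0.0)


class TestDispositionFlux:
    def test_equilibrated_gradient_is_zero(self):
        phys = _phys()
        assert disposition_flux(1.0, phys.void_fraction, phys) == pytest.approx(0.0)

    def test_influx_into_empty_tumor(self):
        assert disposition_flux(1.0, 0.0, _phys()) == pytest.approx(1.082, rel=5e-3)

    def test_efflux_symmetry(self):
        assert disposition_flux(0.0, 0.24, _phys()) == pytest.approx(-1.082, rel=5e-3)


class TestBindingRHS:
    def test_zero_state_zero_derivatives(self):
        state = TumorBindingState(0, 0, 0, 0, tot_cd3_t=1.0, tot_pcad_t=5.0)
        assert binding_rhs(state, _drug(), 0.24) == (0.0, 0.0, 0.0, 0.0)

    def test_equilibrium_oracle_consistency(self):
        """The algebraic equilibrium zeroes the kinetic right-hand side."""
        drug = _drug()
        state = equilibrium_solve(0.5, 0.1, 4.8, drug, 0.24)
        derivs = binding_rhs(state, drug, 0.24, kint_per_h=0.0)
        assert max(abs(d) for d in derivs) < 1e-9

    def test_sum_rule(self):
        """Total drug changes only through disposition and internalization."""
        drug = _drug()
        state = TumorBindingState(0.3, 0.02, 0.5, 0.04, tot_cd3_t=0.1, tot_pcad_t=4.8)
        disp = 0.7
        kint = drug.kint_per_hour
        d = binding_rhs(state, drug, 0.24, disposition=disp, kint_per_h=kint)
        assert sum(d) == pytest.approx(disp - kint * state.dpcadt, abs=1e-12)


class TestEquilibriumSolve:
    def test_zero_drug(self):
        state = equilibrium_solve(0.0, 1.0, 1.0, _drug())
        assert state.dcd3t == state.dpcadt == state.trimer == 0.0

    def test_symmetric_toy_vs_fixed_point_oracle(self):
        """Two independent routes to the same equilibrium."""
        drug = _drug(kon_cd3=1.0, koff_cd3=1.0, kon_pcad=1.0, koff_pcad=1.0)
        state = equilibrium_solve(1.0, 1.0, 1.0, drug, eps=1.0)
        # brute-force fixed-point iteration on the free-receptor pair
        x = y = 1.0
        for _ in range(10_000):
            x = 1.0 / (1.0 + 1.0 + y)   # TotC/(eps + C/KdC + C*y/(KdC*KdP))
            y = 1.0 / (1.0 + 1.0 + x)
        trimer_bf = 1.0 * x * y
        assert state.trimer == pytest.approx(trimer_bf, abs=1e-8)

    def test_excess_drug_suppresses_trimer(self):
        """Dimers dominate at saturating free drug: the bell's right flank."""
        drug = _drug()
        mid = equilibrium_solve(1.0, 0.1, 4.8, drug, 0.24).trimer
        high = equilibrium_solve(1e5, 0.1, 4.8, drug, 0.24).trimer
        assert high < mid * 1e-2

    def test_trimer_vs_free_drug_is_unimodal(self):
        drug = _drug()
        grid = np.logspace(-4, 4, 60)
        trimers = np.array([equilibrium_solve(c, 0.1, 4.8, drug, 0.24).trimer for c in grid])
        i_peak = trimers.argmax()
        assert np.all(np.diff(trimers[: i_peak + 1]) > -1e-15)
        assert np.all(np.diff(trimers[i_peak:]) < 1e-15)

    @pytest.mark.parametrize("seed", range(4))
    def test_kinetic_steady_state_matches_equilibrium(self, seed):
        """Long kinetic integration lands on the algebraic equilibrium."""
        rng = np.random.default_rng(seed)
        drug = _drug(
            kon_cd3=10 ** rng.uniform(-1, 1), koff_cd3=10 ** rng.uniform(-1, 1.5),
            kon_pcad=10 ** rng.uniform(-1, 1), koff_pcad=10 ** rng.uniform(-1, 1),
            kint=0.0,
        )
        tot_c = 10 ** rng.uniform(-2, 1)
        tot_p = 10 ** rng.uniform(-2, 1)
        c_tot = 10 ** rng.uniform(-2, 1)
        eps = rng.uniform(0.1, 1.0)

        def rhs(t, y):
            state = TumorBindingState(y[0], y[1], y[2], y[3], tot_c, tot_p)
            return binding_rhs(state, drug, eps, kint_per_h=0.0)

        sol = solve_ivp(rhs, (0, 5000.0), [c_tot, 0, 0, 0], method="LSODA",
                        rtol=1e-11, atol=1e-13)
        c3_ss, dc_ss, dp_ss, tri_ss = sol.y[:, -1]
        ref = equilibrium_solve(c3_ss, tot_c, tot_p, drug, eps)
        assert tri_ss == pytest.approx(ref.trimer, abs=1e-8)
        assert dc_ss == pytest.approx(ref.dcd3t, abs=1e-8)
        assert dp_ss == pytest.approx(ref.dpcadt, abs=1e-8)

    def test_conservation_in_closed_system(self):
        """No disposition, no internalization: total drug is conserved."""
        drug = _drug(kint=0.0)

        def rhs(t, y):
            state = TumorBindingState(y[0], y[1], y[2], y[3], 0.1, 4.8)
            return binding_rhs(state, drug, 0.24, kint_per_h=0.0)

        total0 = 0.7
        sol = solve_ivp(rhs, (0, 200.0), [total0, 0, 0, 0], method="LSODA",
                        rtol=1e-10, atol=1e-14, dense_output=False)
        totals = sol.y.sum(axis=0)
        assert np.max(np.abs(totals - total0)) / total0 < 1e-8
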