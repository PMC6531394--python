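"""Tumor growth inhibition chain, stasis concentration, and bootstrap CI."""

import numpy as np
import pytest

from trimerqsp import (
    GrowthKillParameters,
    StasisUnreachableError,
    combined_ceff,
    kill_rate,
    simulate_tgi,
    tgi_rhs,
    tsc,
    tsc_confidence_interval,
)
from trimerqsp.errors import InvalidParameterError


def _gk(**kwargs):
    defaults = dict(kg0=0.19, kg=123.0, m_max=6000.0, psi=20.0,
                    kmax=1.32, kc50=6.9e-5, tau=3.99)
    defaults.update(kwargs)
    return GrowthKillParameters(**defaults)


class TestKillRate:
    def test_zero_trimer(self):
        assert kill_rate(0.0, 1.32, 6.9e-5) == 0.0

    def test_half_saturation(self):
        assert kill_rate(6.9e-5, 1.32, 6.9e-5) == pytest.approx(0.66)

    @pytest.mark.parametrize("kg0,kmax,kc50", [(0.19, 1.32, 6.9e-5), (0.30, 0.74, 1e-4), (0.12, 2.71, 2e-4)])
    def test_kill_at_tsc_equals_growth_rate(self, kg0, kmax, kc50):
        """The stasis identity: kkill(TSC) = kg0, exactly."""
        assert kill_rate(tsc(kg0, kmax, kc50), kmax, kc50) == pytest.approx(kg0, rel=1e-12)


class TestTgiRhs:
    def test_exponential_limit(self):
        gk = _gk()
        m = np.array([10.0, 0, 0, 0])  # w far below the switch volume kg/kg0
        dw = tgi_rhs(m, 0.0, gk).sum()
        assert dw == pytest.approx(gk.kg0 * 10.0, rel=1e-2)

    def test_carrying_capacity(self):
        gk = _gk()
        m = np.array([gk.m_max, 0, 0, 0])
        assert tgi_rhs(m, 0.0, gk).sum() == pytest.approx(0.0, abs=1e-9)

    def test_sharp_switch_to_linear_growth(self):
        """Past the switch volume the growth rate approaches kg (mm^3/day)."""
        gk = _gk()
        w_lin = 2.0 * gk.kg / gk.kg0  # twice the crossover volume
        dw = tgi_rhs(np.array([w_lin, 0, 0, 0]), 0.0, gk).sum()
        assert dw == pytest.approx(gk.kg * (1 - w_lin / gk.m_max), rel=5e-2)

    def test_stasis_at_tsc(self):
        """Constant trimer at the TSC holds a small tumor static for a month.

        Small w: the stasis formula balances kill against the exponential
        growth term; the logistic-cap correction (kg0*w/Mmax) is the known
        residual drift and must be negligible at the chosen size.
        """
        gk = _gk()
        level = tsc(gk.kg0, gk.kmax, gk.kc50)
        t = np.linspace(0, 50, 101)
        w = simulate_tgi(lambda _t: level, gk, 10.0, t)[:, 4]
        # after the transit chain reaches quasi-steady state (~several tau),
        # only a small residual drift remains
        drift = abs(np.log(w[-1] / w[60])) / (t[-1] - t[60])
        assert drift < 1e-3

    def test_volume_identity(self):
        """w equals the sum of the four compartments along an integration."""
        gk = _gk()
        t = np.linspace(0, 20, 41)
        out = simulate_tgi(lambda _t: 1e-3, gk, 150.0, t)
        np.testing.assert_allclose(out[:, :4].sum(axis=1), out[:, 4], rtol=1e-12)


class TestTsc:
    @pytest.mark.parametrize(
        "kg0,kmax,kc50,expected_pM",
        [
            (0.19, 1.32, 6.9e-5, 0.0116),
            (0.12, 2.71, 2.0e-4, 0.00927),
            (0.30, 0.74, 1.0e-4, 0.0682),
        ],
    )
    def test_fitted_model_values(self, kg0, kmax, kc50, expected_pM):
        assert tsc(kg0, kmax, kc50) * 1e3 == pytest.approx(expected_pM, rel=1e-2)

    def test_vanishing_growth_needs_no_kill(self):
        assert tsc(1e-12, 1.32, 6.9e-5) == pytest.approx(0.0, abs=1e-12)

    def test_unreachable_stasis(self):
        with pytest.raises(StasisUnreachableError):
            tsc(1.4, 1.32, 6.9e-5)

    def test_monotonicity(self):
        """TSC rises with kg0 and kc50, falls with kmax."""
        kg0s = np.linspace(0.05, 0.5, 8)
        assert np.all(np.diff([tsc(k, 1.32, 6.9e-5) for k in kg0s]) > 0)
        kmaxs = np.linspace(0.6, 3.0, 8)
        assert np.all(np.diff([tsc(0.19, k, 6.9e-5) for k in kmaxs]) < 0)
        kc50s = np.logspace(-5, -3, 8)
        assert np.all(np.diff([tsc(0.19, 1.32, k) for k in kc50s]) > 0)


class TestBootstrapCI:
    EST = {"kg0": 0.19, "kmax": 1.32, "kc50": 6.9e-5}
    CVS = {"kg0": 3.0, "kmax": 7.0, "kc50": 7.0}

    def test_zero_cv_collapses_to_point(self):
        out = tsc_confidence_interval(self.EST, {k: 0.0 for k in self.CVS}, seed=1)
        assert out["lower"] == pytest.approx(out["tsc"])
        assert out["upper"] == pytest.approx(out["tsc"])

    def test_interval_brackets_reported_range(self):
        out = tsc_confidence_interval(self.EST, self.CVS, n_boot=10_000, seed=7)
        assert out["lower"] * 1e3 == pytest.approx(0.0096, rel=0.15)
        assert out["upper"] * 1e3 == pytest.approx(0.013, rel=0.15)
        assert out["discarded_fraction"] == 0.0

    def test_seed_determinism(self):
        a = tsc_confidence_interval(self.EST, self.CVS, n_boot=2000, seed=11)
        b = tsc_confidence_interval(self.EST, self.CVS, n_boot=2000, seed=11)
        assert a == b

    def test_seed_required(self):
        with pytest.raises(InvalidParameterError):
            tsc_confidence_interval(self.EST, self.CVS, seed=None)

    def test_discarded_draws_reported(self):
        est = {"kg0": 1.0, "kmax": 1.05, "kc50": 1e-4}
        out = tsc_confidence_interval(est, {"kg0": 30.0, "kmax": 30.0, "kc50": 5.0},
                                      n_boot=2000, seed=3)
        assert out["n_discarded"] > 0
        assert "warning" in out


class TestCombinedCeff:
    def test_reported_model_tscs(self):
        """Arithmetic and geometric means of the three xenograft TSCs differ
        substantially; both are reported."""
        out = combined_ceff([0.064, 0.011, 0.0092])
        assert out["arithmetic_mean"] == pytest.approx(0.0281, rel=1e-2)
        assert out["geometric_mean"] == pytest.approx(0.0187, rel=1e-2)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            combined_ceff([0.1, -0.2])
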