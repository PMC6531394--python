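"""Estimation machinery: PK fit, per-animal growth, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from trimerqsp import (
    Dataset,
    EstimationError,
    PKParameters,
    ResidualErrorModel,
    dose_to_initial_concentration,
    fit_two_compartment_pk,
    fit_unperturbed_growth,
    two_compartment_closed_form,
)
from trimerqsp.errors import InvalidParameterError
from trimerqsp.fitting import _sign_run_test, growth_curve


def _pk_dataset(pk: PKParameters, mw=105.0, doses=(0.05, 0.5),
                times=(0.083, 1, 6, 24, 48, 96, 168, 240), noise_b=0.0, seed=0,
                n_rep=1):
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        c0 = dose_to_initial_concentration(dose, mw, pk.v1)
        for t in times:
            conc = two_compartment_closed_form(np.array([t]), c0, pk.kel, pk.k12, pk.k21)[0] * mw
            for j in range(n_rep):
                obs = conc * (1 + noise_b * rng.standard_normal())
                rows.append({"id": f"d{dose}t{t}r{j}", "group": str(dose), "dose": dose,
                             "dose_unit": "mg/kg", "time": t, "time_unit": "h",
                             "obs": obs, "obs_type": "serum_conc", "censored": False})
    return Dataset(pd.DataFrame(rows))


class TestTwoCompartmentFit:
    TRUE = PKParameters(v1=49.6, v2=60.7, cl=0.45, cld=4.95)

    def test_noise_free_self_consistency(self):
        """Noise-free synthetic data are recovered almost exactly."""
        ds = _pk_dataset(self.TRUE, noise_b=1e-4, seed=1)
        out = fit_two_compartment_pk(ds, 105.0)
        fitted = out["pk"]
        for name in ("v1", "v2", "cl", "cld"):
            assert getattr(fitted, name) == pytest.approx(getattr(self.TRUE, name), rel=1e-2)

    def test_clearance_recovered_under_noise(self):
        """10% proportional error, triplicate sampling: CL within 10%."""
        ds = _pk_dataset(self.TRUE, noise_b=0.10, seed=7, n_rep=3)
        out = fit_two_compartment_pk(ds, 105.0)
        assert out["pk"].cl == pytest.approx(self.TRUE.cl, rel=0.10)
        assert 0 < out["cv_percent"]["cl"] < 50

    def test_single_time_point_rejected(self):
        ds = _pk_dataset(self.TRUE, times=(24.0,))
        with pytest.raises(EstimationError):
            fit_two_compartment_pk(ds, 105.0)


class TestGrowthCurve:
    def test_matches_adaptive_integration(self):
        from scipy.integrate import solve_ivp

        def rhs(t, y):
            w = y[0]
            return [0.19 * (1 - w / 6000) * w / (1 + (0.19 / 123 * w) ** 20) ** (1 / 20)]

        t = np.arange(0.0, 40.0, 3.5)
        ref = solve_ivp(rhs, (0, t[-1]), [150.0], t_eval=t, rtol=1e-10, atol=1e-10).y[0]
        fast = growth_curve(0.19, 123.0, 6000.0, 20.0, 150.0, t)
        np.testing.assert_allclose(fast, ref, rtol=1e-6)


class TestUnperturbedGrowth:
    def _vehicle(self, kg0s, kg=123.0, w0=150.0, noise=None, seed=0,
                 times=np.arange(0.0, 35.1, 3.5)):
        rng = np.random.default_rng(seed)
        rows = []
        for i, kg0 in enumerate(kg0s):
            w = growth_curve(kg0, kg, 6000.0, 20.0, w0, times)
            for t, v in zip(times, w):
                obs = v if noise is None else v + rng.normal(0, np.sqrt(noise[0]**2 + (noise[1]*v)**2))
                rows.append({"id": f"v{i}", "group": "vehicle", "dose": 0.0,
                             "dose_unit": "mg/kg", "time": t, "time_unit": "day",
                             "obs": max(obs, 10.0), "obs_type": "tumor_volume",
                             "censored": False})
        return Dataset(pd.DataFrame(rows))

    def test_zero_noise_single_animal_exact(self):
        ds = self._vehicle([0.19])
        fit = fit_unperturbed_growth(ds, m_max=6000.0)
        assert fit.kg0_median == pytest.approx(0.19, rel=1e-3)
        assert fit.kg_median == pytest.approx(123.0, rel=1e-3)

    def test_flat_volumes_flagged_at_boundary(self):
        times = np.arange(0.0, 35.1, 3.5)
        rows = [{"id": "flat", "group": "vehicle", "dose": 0.0, "dose_unit": "mg/kg",
                 "time": t, "time_unit": "day", "obs": 150.0,
                 "obs_type": "tumor_volume", "censored": False} for t in times]
        fit = fit_unperturbed_growth(Dataset(pd.DataFrame(rows)), m_max=6000.0)
        assert "flat" in fit.boundary_flags

    def test_too_few_observations_excluded(self):
        times = np.array([0.0, 3.5, 7.0])
        rows = [{"id": "short", "group": "vehicle", "dose": 0.0, "dose_unit": "mg/kg",
                 "time": t, "time_unit": "day", "obs": 150.0 * np.exp(0.19 * t),
                 "obs_type": "tumor_volume", "censored": False} for t in times]
        with pytest.raises(EstimationError):
            fit_unperturbed_growth(Dataset(pd.DataFrame(rows)), m_max=6000.0)

    def test_noisy_cohort_recovers_realized_spread(self):
        rng = np.random.default_rng(11)
        kg0s = 0.19 * np.exp(rng.normal(0, 0.34, size=10))
        ds = self._vehicle(kg0s, noise=(30.0, 0.06), seed=5)
        fit = fit_unperturbed_growth(ds, m_max=6000.0)
        realized_median = np.exp(np.median(np.log(kg0s)))
        assert fit.kg0_median == pytest.approx(realized_median, rel=0.15)
        assert fit.omega_kg0 == pytest.approx(0.34, abs=0.15)


class TestResidualModel:
    def test_sd_combines_terms(self):
        err = ResidualErrorModel(a=60.0, b=0.06)
        np.testing.assert_allclose(err.sd(np.array([0.0, 1000.0])),
                                   [60.0, np.hypot(60.0, 60.0)])

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidParameterError):
            ResidualErrorModel(a=0.0, b=0.0)


class TestSignRunTest:
    def test_alternating_residuals_no_trend(self):
        r = np.array([1.0, -1.0] * 10)
        assert not _sign_run_test(r)["trend_detected"]

    def test_blocked_residuals_flag_trend(self):
        r = np.concatenate([np.ones(10), -np.ones(10)])
        assert _sign_run_test(r)["trend_detected"]
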