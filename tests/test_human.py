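"""Human model: soluble-target homeostasis, linear limit, scans, Ceff coverage."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from trimerqsp import (
    HumanScenario,
    bell_shape_scan,
    compare_to_ceff,
    dose_to_initial_concentration,
    sensitivity_scan,
    simulate_human,
    two_compartment_closed_form,
)
from trimerqsp.errors import InvalidParameterError


class TestHomeostasis:
    def test_soluble_target_stays_at_baseline_without_drug(self, human_params):
        """ksyn = kdeg * baseline keeps shed target flat for 28 days."""
        scen = HumanScenario(dose_ug_per_kg=0.0)
        df = simulate_human(scen, human_params, t_end_h=28 * 24)
        baseline = human_params.soluble_target.spcad_baseline
        drift = np.abs(df["spcad"].to_numpy() / baseline - 1.0)
        assert drift.max() < 1e-6

    def test_drug_depletes_free_soluble_target(self, human_params):
        scen = HumanScenario(dose_ug_per_kg=10.0)
        df = simulate_human(scen, human_params, t_end_h=7 * 24)
        assert df["spcad"].min() < human_params.soluble_target.spcad_baseline * 0.9

    def test_soluble_mass_balance_audit(self, human_params):
        """d(sPcad + complex)/dt = ksyn - kdeg*sPcad - kdegcx*complex,
        audited by finite differences along a simulated trajectory."""
        scen = HumanScenario(dose_ug_per_kg=1.0)
        df = simulate_human(scen, human_params, t_end_h=96.0, n_points=4000,
                            rtol=1e-10, atol=1e-14)
        t = df["time_h"].to_numpy()
        soluble = human_params.soluble_target
        total = df["spcad"].to_numpy() + df["dpcadp"].to_numpy()
        mid = slice(1, -1)
        dtot = np.gradient(total, t)[mid]
        # the drug-binding fluxes cancel in the sum; only synthesis/decay remain
        rhs = (soluble.ksyn - soluble.kdeg * df["spcad"].to_numpy()
               - soluble.kdegcx * df["dpcadp"].to_numpy())[mid]
        scale = max(soluble.ksyn, np.abs(dtot).max())
        assert np.quantile(np.abs(dtot - rhs), 0.95) / scale < 5e-2

    def test_vss_from_loaded_parameters(self, human_params):
        assert human_params.pk.vss == pytest.approx(251.2)


class TestLinearLimit:
    def test_matches_closed_form_without_binding(self, human_params):
        """Zero soluble target, no CD3 binding, no tumor exchange: the serum
        profile collapses to the linear two-compartment solution."""
        soluble = replace(human_params.soluble_target, spcad_baseline=0.0)
        drug = replace(human_params.drug, kon_cd3=1e-12)
        phys = replace(human_params.tumor, permeability=0.0, diffusivity=0.0)
        params = human_params.with_(soluble_target=soluble, drug=drug, tumor=phys)
        scen = HumanScenario(dose_ug_per_kg=1.0, n_doses=1)
        df = simulate_human(scen, params, t_end_h=168.0, n_points=200)
        pk = params.pk
        c0 = dose_to_initial_concentration(1e-3, params.drug.molecular_weight, pk.v1)
        ref = two_compartment_closed_form(df["time_h"].to_numpy(), c0, pk.kel, pk.k12, pk.k21)
        mask = ref > c0 * 1e-8
        assert np.max(np.abs(df["c1"].to_numpy()[mask] - ref[mask]) / ref[mask]) < 1e-3


class TestTrimerKinetics:
    def test_tumor_trimer_peaks_days_after_dose(self, human_params):
        """Tumor uptake is slow: trimer Cmax falls 1-3 days post first dose
        and decays more slowly than serum drug."""
        scen = HumanScenario(dose_ug_per_kg=0.1)
        df = simulate_human(scen, human_params)
        first = df[df["time_h"] <= 168.0]
        tmax_h = first["time_h"].iloc[int(first["trimer"].to_numpy().argmax())]
        assert 24.0 <= tmax_h <= 72.0
        # fractional decline over the rest of the first interval
        serum_decline = first["c1"].iloc[-1] / first["c1"].max()
        trimer_decline = first["trimer"].iloc[-1] / first["trimer"].max()
        assert trimer_decline > serum_decline

    def test_infusion_mode_conserves_dose(self, human_params):
        bolus = simulate_human(HumanScenario(dose_ug_per_kg=0.1, n_doses=1),
                               human_params, t_end_h=168.0)
        infused = simulate_human(
            HumanScenario(dose_ug_per_kg=0.1, n_doses=1, infusion_duration_h=1.0),
            human_params, t_end_h=168.0)
        t = bolus["time_h"].to_numpy()
        auc_b = np.trapezoid(bolus["c1"], t)
        auc_i = np.trapezoid(infused["c1"], infused["time_h"])
        assert auc_i == pytest.approx(auc_b, rel=2e-2)


class TestSensitivityScan:
    def test_trimer_increases_with_receptor_expression(self, human_params):
        scen = HumanScenario(dose_ug_per_kg=0.1)
        table = sensitivity_scan(scen, human_params, "mpcad_per_tumor_cell",
                                 [1000, 3000, 10000, 28706])
        assert table["trimer_cmax_nM"].is_monotonic_increasing

    def test_trimer_increases_with_effector_target_ratio(self, human_params):
        scen = HumanScenario(dose_ug_per_kg=0.1)
        table = sensitivity_scan(scen, human_params, "e_to_t_ratio",
                                 [1 / 1500, 1 / 150, 1 / 15])
        assert table["trimer_cmax_nM"].is_monotonic_increasing

    def test_single_point_grid_matches_simulation(self, human_params):
        scen = HumanScenario(dose_ug_per_kg=0.1)
        table = sensitivity_scan(scen, human_params, "tumor_radius_cm", [1.0])
        assert len(table) == 1
        df = simulate_human(scen, human_params)
        first = df[df["time_h"] <= 168.0]
        assert table["trimer_cmax_nM"].iloc[0] == pytest.approx(first["trimer"].max(), rel=1e-6)

    def test_empty_grid_rejected(self, human_params):
        with pytest.raises(InvalidParameterError):
            sensitivity_scan(HumanScenario(dose_ug_per_kg=0.1), human_params,
                             "e_to_t_ratio", [])


class TestCeffCoverage:
    def test_zero_trimer_zero_coverage(self):
        df = pd.DataFrame({"time_h": np.linspace(0, 168, 50),
                           "trimer_pM": np.zeros(50)})
        assert compare_to_ceff(df, 0.028)["coverage_fraction"] == 0.0

    def test_constant_above_threshold_full_coverage(self):
        df = pd.DataFrame({"time_h": np.linspace(0, 168, 50),
                           "trimer_pM": np.full(50, 0.056)})
        assert compare_to_ceff(df, 0.028)["coverage_fraction"] == pytest.approx(1.0)

    def test_coverage_monotone_in_dose_below_bell_peak(self, human_params):
        covs = []
        for dose in [0.003, 0.01, 0.03]:
            df = simulate_human(HumanScenario(dose_ug_per_kg=dose), human_params,
                                t_end_h=21 * 24)
            covs.append(compare_to_ceff(df, 0.028)["coverage_fraction"])
        assert covs == sorted(covs)

    def test_invalid_threshold(self):
        df = pd.DataFrame({"time_h": [0.0, 1.0], "trimer_pM": [0.0, 0.0]})
        with pytest.raises(InvalidParameterError):
            compare_to_ceff(df, 0.0)


class TestBellShape:
    def test_no_receptors_no_peak(self, human_params):
        cells = replace(human_params.cells, mpcad_per_tumor_cell=0.0)
        params = human_params.with_(cells=cells)
        scen = HumanScenario(dose_ug_per_kg=0.0, n_doses=2)
        peak, table = bell_shape_scan(params, scen,
                                      dose_grid_ug_per_kg=np.logspace(0, 2, 4),
                                      metric_interval=1)
        assert np.isnan(peak)
        assert "warning" in table.attrs

    def test_equilibrium_toy_peak_matches_kinetic_intuition(self, human_params):
        """A single-compartment equilibrium scan over free drug shows the
        same bell shape the kinetic dose scan produces."""
        from trimerqsp import equilibrium_solve

        drug = human_params.drug
        grid = np.logspace(-3, 3, 40)
        trimers = [equilibrium_solve(c, 0.108, 4.77, drug, 0.24).trimer for c in grid]
        i = int(np.argmax(trimers))
        assert 0 < i < len(grid) - 1  # interior maximum: a genuine bell
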