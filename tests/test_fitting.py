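"""Constitutive fits: exact recovery, noisy recovery, degenerate designs."""

import numpy as np
import pandas as pd
import pytest

from electrokin.constitutive import Combination, DielectricModel, ViscosityModel
from electrokin.fitting import (
    FitError,
    MeasurementTable,
    compare_combination_models,
    fit_booth,
    fit_eta_conc,
    fit_eta_field,
    fit_gavish_promislow,
)
from electrokin.synth import (
    SyntheticConfig,
    gen_dielectric_table,
    gen_viscosity_table,
)


def _noise_free_tables(dielectric=None, viscosity=None):
    cfg = SyntheticConfig(
        seed=0,
        E0_grid=(0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
        c0_grid=(0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
        dielectric=dielectric or DielectricModel(),
        viscosity=viscosity or ViscosityModel())
    return gen_dielectric_table(cfg), gen_viscosity_table(cfg)


class TestMeasurementTable:
    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame({
            "E0_V_per_nm": [0.0, 0.0], "c0_M": [1.0, 1.0],
            "component": ["parallel"] * 2, "quantity": ["eta"] * 2,
            "value": [0.7, 0.8]})
        with pytest.raises(ValueError, match="duplicate"):
            MeasurementTable(df)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MeasurementTable(pd.DataFrame(columns=list(
                ("E0_V_per_nm", "c0_M", "component", "quantity", "value"))))


class TestGavishPromislow:
    def test_exact_recovery_of_literature_values(self):
        table, _ = _noise_free_tables()
        res = fit_gavish_promislow(table, eps_w_fixed=71.0)
        assert res.params["eps_ms"] == pytest.approx(27.9, rel=1e-6)
        assert res.params["alpha"] == pytest.approx(-11.59, rel=1e-6)

    def test_noisy_recovery_within_three_stderr(self):
        cfg = SyntheticConfig(seed=21, c0_grid=tuple(np.linspace(0, 4, 20)),
                              noise_eps=0.5)
        table = gen_dielectric_table(cfg)
        res = fit_gavish_promislow(table, eps_w_fixed=71.0)
        assert abs(res.params["eps_ms"] - 27.9) < 3 * res.stderr("eps_ms")
        assert abs(res.params["a_c"] - DielectricModel().a_c) < 3 * res.stderr("a_c")

    def test_flat_table_yields_zero_decrement(self):
        rows = [{"E0_V_per_nm": 0.0, "c0_M": c, "component": "parallel",
                 "quantity": "eps_diff", "value": 71.0}
                for c in (0.0, 0.5, 1.0, 2.0, 4.0)]
        res = fit_gavish_promislow(MeasurementTable(pd.DataFrame(rows)), 71.0)
        # (eps_ms, a_c) are jointly unidentifiable on a flat line; the
        # identifiable decrement slope alpha = a_c (eps_w - eps_ms)/3 is zero
        assert abs(res.params["alpha"]) < 1e-6
        assert abs(res.params["a_c"]) < 1e-3

    def test_too_few_concentrations_rejected(self):
        rows = [{"E0_V_per_nm": 0.0, "c0_M": c, "component": "parallel",
                 "quantity": "eps_diff", "value": 70.0} for c in (0.0, 1.0)]
        with pytest.raises(FitError):
            fit_gavish_promislow(MeasurementTable(pd.DataFrame(rows)), 71.0)


class TestBooth:
    def test_exact_self_recovery(self):
        table, _ = _noise_free_tables()
        res = fit_booth(table, eps_w_fixed=71.0)
        assert res.params["eps_n"] == pytest.approx(4.0, rel=1e-6)
        assert res.params["a_E"] == pytest.approx(10.0, rel=1e-6)

    def test_noisy_recovery_within_three_stderr(self):
        cfg = SyntheticConfig(seed=22, E0_grid=tuple(np.linspace(0, 3, 15)),
                              noise_eps=1.0)
        table = gen_dielectric_table(cfg)
        res = fit_booth(table, eps_w_fixed=71.0)
        assert abs(res.params["eps_n"] - 4.0) < 3 * res.stderr("eps_n")
        assert abs(res.params["a_E"] - 10.0) < 3 * res.stderr("a_E")

    def test_flat_table_flags_boundary_instead_of_crashing(self):
        rows = [{"E0_V_per_nm": E, "c0_M": 0.0, "component": "parallel",
                 "quantity": "eps_diff", "value": 71.0}
                for E in (0.0, 0.5, 1.0, 2.0)]
        res = fit_booth(MeasurementTable(pd.DataFrame(rows)), 71.0)
        assert res.at_boundary


class TestEtaFits:
    def test_printed_salt_coefficients_to_1e8(self):
        cfg = SyntheticConfig(seed=0, E0_grid=(0.0,),
                              c0_grid=tuple(np.arange(0.0, 2.01, 0.25)))
        table = gen_viscosity_table(cfg)
        res = fit_eta_conc(table, eta_w_fixed=0.648)
        assert res.params["a_c1"] == pytest.approx(0.0777, abs=1e-8)
        assert res.params["a_c2"] == pytest.approx(0.0223, abs=1e-8)

    def test_cofit_eta_w_when_unfixed(self):
        _, table = _noise_free_tables()
        res = fit_eta_conc(table, eta_w_fixed=None)
        assert res.params["eta_w"] == pytest.approx(0.648, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        rows = [{"E0_V_per_nm": 0.0, "c0_M": c, "component": "parallel",
                 "quantity": "eta", "value": 0.7} for c in (0.0, 1.0)]
        with pytest.raises(FitError):
            fit_eta_conc(MeasurementTable(pd.DataFrame(rows)), eta_w_fixed=None)

    def test_noisy_salt_recovery_within_three_stderr(self):
        cfg = SyntheticConfig(seed=23, E0_grid=(0.0,),
                              c0_grid=tuple(np.linspace(0, 4, 20)),
                              noise_eta=0.005)
        table = gen_viscosity_table(cfg)
        res = fit_eta_conc(table, eta_w_fixed=0.648)
        assert abs(res.params["a_c1"] - 0.0777) < 3 * res.stderr("a_c1")
        assert abs(res.params["a_c2"] - 0.0223) < 3 * res.stderr("a_c2")

    @pytest.mark.parametrize("component, a1, a2", [
        ("parallel", 0.160, 0.0868),
        ("perpendicular", -0.190, 0.0319),
    ])
    def test_printed_field_coefficients(self, component, a1, a2):
        cfg = SyntheticConfig(seed=0, c0_grid=(0.0,),
                              E0_grid=tuple(np.arange(0.0, 2.01, 0.25)))
        table = gen_viscosity_table(cfg)
        res = fit_eta_field(table, component, eta_w_fixed=0.648)
        assert res.params["a_E1"] == pytest.approx(a1, rel=1e-6)
        assert res.params["a_E2"] == pytest.approx(a2, rel=1e-6)

    def test_recovered_sign_matches_initial_slope(self):
        _, table = _noise_free_tables()
        for comp, sign in (("parallel", 1), ("perpendicular", -1)):
            res = fit_eta_field(table, comp)
            assert np.sign(res.params["a_E1"]) == sign


class TestCombinationComparison:
    def test_multiplicative_truth_is_ranked_first(self):
        table, vtable = _noise_free_tables()
        for t, kind in ((table, "dielectric"), (vtable, "viscosity")):
            ranking = compare_combination_models(t, kind)
            assert ranking.loc[0, "mode"] == "multiplicative"
            assert ranking.loc[0, "rss"] < ranking.loc[1, "rss"]

    def test_additive_truth_is_ranked_first(self):
        d = DielectricModel(combination=Combination.ADDITIVE)
        v = ViscosityModel(combination=Combination.ADDITIVE)
        table, vtable = _noise_free_tables(d, v)
        for t, kind in ((table, "dielectric"), (vtable, "viscosity")):
            ranking = compare_combination_models(t, kind)
            assert ranking.loc[0, "mode"] == "additive"

    def test_axes_only_table_ties_toward_multiplicative(self):
        # ansatze coincide on the axes: equal rss, multiplicative first
        rows = []
        d = DielectricModel()
        from electrokin.constitutive import eps_combined
        for E in (0.0, 0.5, 1.0, 2.0):
            rows.append({"E0_V_per_nm": E, "c0_M": 0.0, "component": "parallel",
                         "quantity": "eps_diff",
                         "value": float(eps_combined(E, 0.0, d))})
        for c in (0.5, 1.0, 2.0, 4.0):
            rows.append({"E0_V_per_nm": 0.0, "c0_M": c, "component": "parallel",
                         "quantity": "eps_diff",
                         "value": float(eps_combined(0.0, c, d))})
        ranking = compare_combination_models(
            MeasurementTable(pd.DataFrame(rows)), "dielectric")
        assert ranking.loc[0, "rss"] == pytest.approx(ranking.loc[1, "rss"],
                                                      abs=1e-16)
        assert ranking.loc[0, "mode"] == "multiplicative"

    def test_degenerate_grid_rejected(self):
        rows = [{"E0_V_per_nm": 0.0, "c0_M": c, "component": "parallel",
                 "quantity": "eps_diff", "value": 70.0}
                for c in (0.0, 0.5, 1.0, 2.0)]
        with pytest.raises(FitError, match="grid"):
            compare_combination_models(
                MeasurementTable(pd.DataFrame(rows)), "dielectric")
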