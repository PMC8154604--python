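"""Constitutive laws: anchor points, limits, coupling and profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from electrokin.constitutive import (
    Combination,
    Component,
    DielectricModel,
    InterfaceSpec,
    ProfileMode,
    ViscosityModel,
    eps_combined,
    eps_field_diff,
    eps_profile,
    eps_salt,
    eta_combined,
    eta_field,
    eta_profile,
    eta_salt,
)


class TestDielectricSalt:
    def test_zero_salt_is_pure_water(self, dielectric):
        assert eps_salt(0.0, dielectric) == pytest.approx(71.0)

    def test_high_salt_saturates(self, dielectric):
        assert eps_salt(1e6, dielectric) == pytest.approx(27.9, abs=1e-3)

    def test_initial_slope_is_alpha(self, dielectric):
        # small-c Taylor expansion: eps(c) ~ eps_w + alpha c
        c = 0.01
        expected = 71.0 + (-11.59) * c  # ~70.88
        assert eps_salt(c, dielectric) == pytest.approx(expected, abs=2e-3)

    def test_monotone_decreasing(self, dielectric):
        c = np.linspace(0.0, 10.0, 200)
        assert np.all(np.diff(eps_salt(c, dielectric)) < 0)

    def test_negative_concentration_rejected(self, dielectric):
        with pytest.raises(ValueError):
            eps_salt(-0.1, dielectric)

    def test_a_c_alpha_relation(self, dielectric):
        assert dielectric.a_c == pytest.approx(
            3 * dielectric.alpha / (dielectric.eps_w - dielectric.eps_ms))


class TestDielectricField:
    def test_zero_field_is_pure_water(self, dielectric):
        assert eps_field_diff(0.0, dielectric) == pytest.approx(71.0)

    def test_high_field_saturates(self, dielectric):
        assert eps_field_diff(1e6, dielectric) == pytest.approx(
            dielectric.eps_n, abs=1e-3)

    def test_even_in_signed_field(self, dielectric):
        E = np.array([0.3, 1.2, 3.7])
        assert eps_field_diff(-E, dielectric) == pytest.approx(
            eps_field_diff(E, dielectric))

    @pytest.mark.parametrize("E0", [0.1, 0.5, 1.0, 3.0])
    def test_is_running_average_of_differential_constant(self, dielectric, E0):
        """epsbar(E) = (1/E) int_0^E d(E' epsbar)/dE' dE' to 1e-6 relative."""
        h = 1e-7

        def differential(E):
            return ((E + h) * eps_field_diff(E + h, dielectric)
                    - (E - h) * eps_field_diff(E - h, dielectric)) / (2 * h)

        integral, _ = quad(differential, 0.0, E0, limit=200)
        assert integral / E0 == pytest.approx(
            eps_field_diff(E0, dielectric), rel=1e-6)


class TestDielectricCombined:
    def test_anchor_point_both_modes(self, dielectric):
        add = DielectricModel(combination=Combination.ADDITIVE)
        assert eps_combined(0.0, 0.0, dielectric) == pytest.approx(71.0)
        assert eps_combined(0.0, 0.0, add) == pytest.approx(71.0)

    def test_marginal_consistency(self, dielectric):
        assert eps_combined(1.3, 0.0, dielectric) == pytest.approx(
            eps_field_diff(1.3, dielectric))
        assert eps_combined(0.0, 2.5, dielectric) == pytest.approx(
            eps_salt(2.5, dielectric))

    def test_multiplicative_bounded_below_by_one(self, dielectric):
        assert eps_combined(1e6, 1e6, dielectric) >= 1.0
        E, c = np.meshgrid(np.linspace(0, 10, 30), np.linspace(0, 10, 30))
        assert np.all(eps_combined(E, c, dielectric) >= 1.0)

    def test_unknown_mode_is_config_error(self, dielectric):
        from dataclasses import replace
        bad = replace(dielectric, combination="geometric")
        with pytest.raises(ValueError):
            eps_combined(1.0, 1.0, bad)


class TestViscosity:
    def test_zero_is_water(self, viscosity):
        assert eta_salt(0.0, viscosity) == pytest.approx(0.648)
        for comp in Component:
            assert eta_field(0.0, comp, viscosity) == pytest.approx(0.648)

    @pytest.mark.parametrize("c0, expected", [(1.0, 0.748), (2.0, 0.8926)])
    def test_salt_polynomial_printed_coefficients(self, viscosity, c0, expected):
        assert eta_salt(c0, viscosity) == pytest.approx(expected, abs=1e-4)

    def test_salt_monotone_increasing(self, viscosity):
        c = np.linspace(0, 4, 100)
        assert np.all(np.diff(eta_salt(c, viscosity)) > 0)

    def test_perpendicular_dips_below_water(self, viscosity):
        E = np.linspace(0, 4, 400)
        eta = eta_field(E, Component.PERPENDICULAR, viscosity)
        imin = np.argmin(eta)
        assert 0 < imin < len(E) - 1
        assert eta[imin] < viscosity.eta_w

    def test_parallel_high_field_asymptote(self, viscosity):
        """Beyond dipole saturation, eta - eta_w - a_E1 grows as a_E2 E^2."""
        E = 4.0
        excess = (eta_field(E, Component.PARALLEL, viscosity)
                  - viscosity.eta_w - viscosity.a_E1_par)
        assert excess == pytest.approx(viscosity.a_E2_par * E**2, rel=0.05)

    def test_combined_modes_and_identity(self, viscosity):
        from dataclasses import replace
        add = replace(viscosity, combination=Combination.ADDITIVE)
        E0, c0 = 0.5, 1.0
        for m in (viscosity, add):
            assert eta_combined(0.0, 0.0, "parallel", m) == pytest.approx(0.648)
            assert eta_combined(E0, 0.0, "parallel", m) == pytest.approx(
                eta_field(E0, "parallel", m))
        # multiplicative - additive = (eta_E - eta_w)(eta_c - eta_w)/eta_w
        diff = (eta_combined(E0, c0, "perpendicular", viscosity)
                - eta_combined(E0, c0, "perpendicular", add))
        expected = ((eta_field(E0, "perpendicular", viscosity) - 0.648)
                    * (eta_salt(c0, viscosity) - 0.648) / 0.648)
        assert diff == pytest.approx(expected, rel=1e-10)

    def test_unknown_component_rejected(self, viscosity):
        with pytest.raises(ValueError):
            eta_field(1.0, "diagonal", viscosity)


class TestProfiles:
    def test_box_overrides_near_wall(self, dielectric, viscosity):
        spec = InterfaceSpec(profile_mode=ProfileMode.EXTENDED_BOX)
        assert eps_profile(1.0, 0.5, 0.2, spec, dielectric) == 4.4
        assert eta_profile(1.0, 0.5, 0.2, spec, viscosity) == pytest.approx(
            3.7 * 0.648)

    def test_far_field_recovers_bulk_water(self, dielectric, viscosity):
        spec = InterfaceSpec(profile_mode=ProfileMode.EXTENDED_BOX)
        assert eps_profile(0.0, 0.0, 10.0, spec, dielectric) == pytest.approx(71.0)
        assert eta_profile(0.0, 0.0, 10.0, spec, viscosity) == pytest.approx(0.648)

    def test_bulk_like_ignores_z(self, dielectric):
        spec = InterfaceSpec(profile_mode=ProfileMode.BULK_LIKE)
        assert eps_profile(0.0, 0.5, 0.01, spec, dielectric) == pytest.approx(
            eps_salt(0.5, dielectric))

    @given(z=st.floats(0.0, 5.0), E=st.floats(0.0, 3.0), c=st.floats(0.0, 3.0))
    def test_zero_width_box_reduces_to_bulk_like(self, z, E, c):
        d, v = DielectricModel(), ViscosityModel()
        box0 = InterfaceSpec(z_int=0.0, profile_mode=ProfileMode.EXTENDED_BOX)
        bulk = InterfaceSpec(profile_mode=ProfileMode.BULK_LIKE)
        assert eps_profile(E, c, z, box0, d) == eps_profile(E, c, z, bulk, d)
        assert eta_profile(E, c, z, box0, v) == eta_profile(E, c, z, bulk, v)

    def test_perpendicular_component_used_in_eta_profile(self, viscosity):
        spec = InterfaceSpec(profile_mode=ProfileMode.BULK_LIKE)
        E = 1.5
        assert eta_profile(E, 0.0, 1.0, spec, viscosity) == pytest.approx(
            eta_field(E, Component.PERPENDICULAR, viscosity))
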