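"""Unit and property tests for fluid rheology and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsuleflow.params import (
    CellParams,
    ChannelSpec,
    DimensionlessGroups,
    FluidModel,
    dimensionless_groups,
    mean_duct_speed,
    power_law_viscosity,
    propagate_uncertainty,
    to_dimensional,
)

FLUID_CONSTRICTED = FluidModel(mu0=32.7e-3)
FLUID_CROSS = FluidModel(mu0=33.9e-3)


class TestPowerLawViscosity:
    @pytest.mark.parametrize(
        "gamma_dot, expected, rtol",
        [
            (1.0, 0.053, 1e-12),  # consistency at the reference shear rate
            (100.0, 0.053 * 100.0 ** (-0.05), 1e-12),
            (0.0, 0.053 * 0.01 ** (-0.05), 1e-12),  # clamped at gamma_min
        ],
    )
    def test_values(self, gamma_dot, expected, rtol):
        assert power_law_viscosity(gamma_dot, FLUID_CONSTRICTED) == pytest.approx(
            expected, rel=rtol)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            power_law_viscosity(np.nan, FLUID_CONSTRICTED)
        with pytest.raises(ValueError):
            power_law_viscosity(-1.0, FLUID_CONSTRICTED)

    @given(st.floats(min_value=1e-4, max_value=1e7),
           st.floats(min_value=1e-4, max_value=1e7))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_for_shear_thinning(self, g1, g2):
        lo, hi = sorted((g1, g2))
        assert (power_law_viscosity(lo, FLUID_CONSTRICTED)
                >= power_law_viscosity(hi, FLUID_CONSTRICTED) - 1e-15)

    def test_constant_for_newtonian(self):
        newt = FluidModel(K=0.03, alpha=1.0, mu0=0.03)
        g = np.logspace(-2, 5, 20)
        mu = power_law_viscosity(g, newt)
        assert np.allclose(mu, 0.03)


class TestDimensionlessGroups:
    def test_pc3_constricted_groups(self):
        cell = CellParams(a=7.4e-6, Gs=10.355e-3, C=10.0,
                          mu_s=19.36e-6, mu_c=32.7e-3)
        chan = ChannelSpec(kind="constricted", l=20e-6, U=0.19)
        g = dimensionless_groups(FLUID_CONSTRICTED, cell, chan)
        assert g.Ca == pytest.approx(0.60, rel=1e-3)
        assert g.eta == pytest.approx(80.0, rel=1e-2)
        assert g.lam == pytest.approx(1.0)
        assert g.confinement == pytest.approx(0.74)
        assert g.Re == pytest.approx(0.123, rel=0.01)  # reported ~0.12

    def test_cross_slot_reynolds(self):
        cell = CellParams(a=8.6e-6, Gs=5.763e-3, C=10.0, mu_c=33.9e-3)
        chan = ChannelSpec(kind="cross_slot", l=40e-6, U=0.17)
        g = dimensionless_groups(FLUID_CROSS, cell, chan)
        assert g.Re == pytest.approx(0.213, rel=0.01)  # reported ~0.21

    def test_zero_membrane_viscosity(self):
        cell = CellParams(a=7.4e-6, Gs=1e-2, C=1.0, mu_s=0.0)
        chan = ChannelSpec(kind="constricted", l=20e-6, U=0.19)
        assert dimensionless_groups(FLUID_CONSTRICTED, cell, chan).eta == 0.0

    @given(st.floats(min_value=0.02, max_value=2.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_scaling_in_speed(self, U):
        cell = CellParams(a=7.4e-6, Gs=1e-2, C=1.0)
        g = dimensionless_groups(
            FLUID_CONSTRICTED, cell,
            ChannelSpec(kind="constricted", l=20e-6, U=U))
        g1 = dimensionless_groups(
            FLUID_CONSTRICTED, cell,
            ChannelSpec(kind="constricted", l=20e-6, U=1.0))
        assert g.Ca == pytest.approx(U * g1.Ca, rel=1e-12)
        assert g.Re == pytest.approx(U * g1.Re, rel=1e-12)


class TestDimensionalConversion:
    def test_pc3_constricted_moduli(self):
        g = DimensionlessGroups(Ca=0.6, C=10.0, eta=80.0)
        Gs, Ks, mu_s = to_dimensional(g, FLUID_CONSTRICTED, 0.19, 7.4e-6)
        assert Gs * 1e3 == pytest.approx(10.4, abs=0.05)
        assert Ks * 1e3 == pytest.approx(217.0, rel=0.005)
        assert mu_s * 1e6 == pytest.approx(19.4, abs=0.05)

    def test_k562_cell1_moduli(self):
        g = DimensionlessGroups(Ca=1.4, C=10.0, eta=40.0)
        Gs, Ks, mu_s = to_dimensional(g, FLUID_CONSTRICTED, 0.19, 6.0e-6)
        assert Gs * 1e3 == pytest.approx(4.4, abs=0.05)
        assert Ks * 1e3 == pytest.approx(93.0, rel=0.01)
        assert mu_s * 1e6 == pytest.approx(7.8, abs=0.1)

    def test_round_trip(self):
        g = DimensionlessGroups(Ca=0.6, C=10.0, eta=80.0, lam=1.0,
                                confinement=0.74)
        Gs, Ks, mu_s = to_dimensional(g, FLUID_CONSTRICTED, 0.19, 7.4e-6)
        cell = CellParams(a=7.4e-6, Gs=Gs, C=10.0, mu_s=mu_s,
                          mu_c=32.7e-3)
        back = dimensionless_groups(
            FLUID_CONSTRICTED, cell,
            ChannelSpec(kind="constricted", l=20e-6, U=0.19))
        assert back.Ca == pytest.approx(g.Ca, rel=1e-12)
        assert back.eta == pytest.approx(g.eta, rel=1e-12)

    def test_rejects_zero_ca(self):
        with pytest.raises(ValueError):
            to_dimensional(DimensionlessGroups(Ca=0.0, C=1.0),
                           FLUID_CONSTRICTED, 0.19, 7e-6)

    @given(st.floats(min_value=0.5, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_ks_identity(self, C):
        cell = CellParams(a=5e-6, Gs=2e-3, C=C)
        assert cell.Ks == pytest.approx((1 + 2 * C) * cell.Gs, rel=1e-14)


class TestFlowConditions:
    def test_constricted_mean_speed(self):
        # 1.5 + 3 ul/min of cell suspension plus sheath flow
        Q = 4.5e-9 / 60.0
        assert mean_duct_speed(Q, 20e-6) == pytest.approx(0.1875, rel=1e-10)

    def test_cross_slot_mean_speed(self):
        Q = 16e-9 / 60.0
        assert mean_duct_speed(Q, 40e-6) == pytest.approx(1 / 6, rel=1e-10)

    def test_zero_flow(self):
        assert mean_duct_speed(0.0, 20e-6) == 0.0

    def test_channelspec_derives_speed(self):
        chan = ChannelSpec(kind="cross_slot", l=40e-6, Q=16e-9 / 60.0)
        assert chan.U == pytest.approx(0.1667, rel=1e-3)


class TestUncertaintyPropagation:
    def test_pc3_reported_uncertainties(self):
        dGs, dKs, dmu_s = propagate_uncertainty(
            (0.6, 10.0, 80.0), (0.1, 1.0, 5.0),
            FLUID_CONSTRICTED, 0.19, 7.4e-6)
        assert dGs * 1e3 == pytest.approx(0.9, abs=0.05)
        assert dKs * 1e3 == pytest.approx(21.0, abs=0.5)
        assert dmu_s * 1e6 == pytest.approx(0.6, abs=0.05)

    def test_zero_eta_reports_half_increment_bound(self):
        _, _, dmu_s = propagate_uncertainty(
            (0.6, 10.0, 0.0), (0.1, 1.0, 5.0),
            FLUID_CONSTRICTED, 0.19, 7.4e-6)
        assert dmu_s == pytest.approx(2.5 * 32.7e-3 * 7.4e-6)

    def test_rejects_zero_best_fit(self):
        with pytest.raises(ValueError):
            propagate_uncertainty((0.0, 10.0, 5.0), (0.1, 1.0, 5.0),
                                  FLUID_CONSTRICTED, 0.19, 7.4e-6)


class TestValidation:
    def test_cell_defaults(self):
        cell = CellParams(a=7.4e-6, Gs=1e-2, C=10.0)
        assert cell.kc == pytest.approx(0.001 * 1e-2 * (7.4e-6) ** 2)
        assert cell.Gsn == pytest.approx(2e-2)
        assert cell.a_n == pytest.approx(3.7e-6)
        assert cell.Ksn == pytest.approx(21 * 2e-2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FluidModel(K=-1.0)
        with pytest.raises(ValueError):
            FluidModel(alpha=1.5)
        with pytest.raises(ValueError):
            CellParams(a=-1e-6, Gs=1e-2, C=1.0)
        with pytest.raises(ValueError):
            ChannelSpec(kind="weird", l=20e-6, U=0.1)
        with pytest.raises(ValueError):
            DimensionlessGroups(Ca=-0.5, C=1.0)


class TestCrossSectionAverage:
    def test_area_average_near_reported_mu0(self):
        """The area-average power-law viscosity over the duct section lands
        within ~10 % of the measured characteristic viscosity (the exact
        averaging convention behind the reported value is unstated)."""
        from capsuleflow.params import cross_section_average_viscosity

        mu_area = cross_section_average_viscosity(FLUID_CONSTRICTED, 0.19,
                                                  20e-6)
        assert mu_area == pytest.approx(32.7e-3, rel=0.10)
        mu_flow = cross_section_average_viscosity(FLUID_CONSTRICTED, 0.19,
                                                  20e-6, flow_weighted=True)
        assert mu_flow == pytest.approx(32.7e-3, rel=0.10)
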