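import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from headfsi.materials import (
    ElasticFluidParams,
    MieGruneisenParams,
    ViscousParams,
    bulk_sound_speed,
    compression_mu,
    effective_viscosity_ratio,
    elastic_fluid_deviatoric,
    elastic_fluid_pressure_rate,
    gruneisen_pressure,
    newtonian_deviatoric,
)

WATER = MieGruneisenParams()
# independent high-precision evaluation of the Hugoniot expression at the
# water constants, frozen as the oracle value
P_MU_001 = 22324338.7490012


class TestElasticFluid:
    def test_pressure_rate_examples(self):
        p = ElasticFluidParams()
        assert elastic_fluid_pressure_rate(p, 0.0) == 0.0
        assert elastic_fluid_pressure_rate(p, -1e-3) == pytest.approx(2.19e6)
        assert elastic_fluid_pressure_rate(p, -1.0) > 0  # compression raises P

    def test_bulk_sound_speed(self):
        assert bulk_sound_speed(2.19e9, 1000.0) == pytest.approx(1479.86485869, rel=1e-9)
        assert bulk_sound_speed(4.0, 4.0) == 1.0
        assert bulk_sound_speed(4 * 2.19e9, 1000.0) == pytest.approx(
            2 * bulk_sound_speed(2.19e9, 1000.0))
        with pytest.raises(ValueError):
            bulk_sound_speed(-1.0, 1000.0)

    def test_deviatoric_example(self):
        p = ElasticFluidParams(K=2.19e9, VC=0.3, rho=1000.0, delta_L=1e-3)
        assert elastic_fluid_deviatoric(p, 1.0) == pytest.approx(443.959457608, rel=1e-9)
        assert elastic_fluid_deviatoric(p, 0.0) == 0.0
        doubled = ElasticFluidParams(K=2.19e9, VC=0.3, rho=1000.0, delta_L=2e-3)
        assert elastic_fluid_deviatoric(doubled, 1.0) == pytest.approx(
            2 * elastic_fluid_deviatoric(p, 1.0))

    def test_vc_warning_band(self):
        with pytest.warns(UserWarning):
            ElasticFluidParams(VC=0.8)


class TestMieGruneisen:
    def test_compression_mu(self):
        assert compression_mu(1000.0, 1000.0) == 0.0
        assert compression_mu(1010.0, 1000.0) == pytest.approx(0.01)
        assert compression_mu(500.0, 1000.0) == pytest.approx(-0.5)

    def test_reference_state_is_zero(self):
        assert gruneisen_pressure(WATER, 0.0, 0.0) == 0.0

    def test_hugoniot_matches_independent_evaluation(self):
        assert gruneisen_pressure(WATER, 0.01, 0.0) == pytest.approx(P_MU_001, rel=1e-12)

    def test_cutoff_floor(self):
        # strong expansion: the raw expression is far below -22 MPa
        assert gruneisen_pressure(WATER, -0.2, 0.0) == WATER.p_cut
        # the floor holds for any admissible input
        for mu in np.linspace(-0.4, 0.4, 81):
            assert gruneisen_pressure(WATER, float(mu)) >= WATER.p_cut

    def test_energy_term_switch(self):
        e = 1e5
        with_e = gruneisen_pressure(WATER, 0.01, e, energy_term=True)
        without = gruneisen_pressure(WATER, 0.01, e, energy_term=False)
        assert with_e - without == pytest.approx(WATER.gamma0 * e)
        assert without == pytest.approx(gruneisen_pressure(WATER, 0.01, 0.0))

    def test_small_compression_acoustic_limit(self):
        """P ~ rho0 C^2 mu as mu -> 0, within 0.1% at mu = 1e-6."""
        mu = 1e-6
        p = gruneisen_pressure(WATER, mu, 0.0)
        acoustic = WATER.rho0 * WATER.C**2 * mu
        assert p == pytest.approx(acoustic, rel=1e-3)

    def test_out_of_range_compression_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            gruneisen_pressure(WATER, 1.5, 0.0)

    @given(st.floats(min_value=-0.3, max_value=0.5))
    @settings(max_examples=50, deadline=None)
    def test_continuity_in_mu(self, mu):
        eps = 1e-9
        p0 = gruneisen_pressure(WATER, mu, 0.0, apply_cutoff=False)
        p1 = gruneisen_pressure(WATER, mu + eps, 0.0, apply_cutoff=False)
        # local Lipschitz bound: slope never exceeds ~100x the acoustic modulus
        assert abs(p1 - p0) < 100 * WATER.rho0 * WATER.C**2 * eps + 1e-6


class TestViscousContrast:
    def test_newtonian_example(self):
        vp = ViscousParams(gamma=0.001)
        assert newtonian_deviatoric(vp, 1.0) == pytest.approx(0.001)
        assert newtonian_deviatoric(vp, 0.0) == 0.0
        assert newtonian_deviatoric(vp, 2.0) == pytest.approx(
            2 * newtonian_deviatoric(vp, 1.0))

    def test_tracefree_enforced(self):
        bad = np.diag([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            newtonian_deviatoric(ViscousParams(), bad)

    def test_both_laws_return_tracefree_tensors(self):
        dev = np.array([[2.0, 0.5, 0.0], [0.5, -1.0, 0.0], [0.0, 0.0, -1.0]])
        for out in (newtonian_deviatoric(ViscousParams(), dev),
                    elastic_fluid_deviatoric(ElasticFluidParams(), dev)):
            assert abs(np.trace(out)) <= 1e-9 * np.max(np.abs(out))

    def test_effective_viscosity_ratio_closed_form(self):
        ef = ElasticFluidParams(K=2.19e9, VC=0.3, rho=1000.0, delta_L=1e-3)
        ratio = effective_viscosity_ratio(ef, ViscousParams(0.001))
        assert ratio == pytest.approx(443959.4576, rel=1e-9)

    def test_ratio_exceeds_three_orders_at_defaults(self):
        """The stress-contrast mechanism behind the two CSF treatments."""
        ratio = effective_viscosity_ratio(ElasticFluidParams(), ViscousParams())
        assert ratio >= 1e3

    def test_unit_ratio_when_viscosities_match(self):
        ef = ElasticFluidParams(delta_L=1e-3)
        gamma = ef.VC * ef.delta_L * ef.sound_speed * ef.rho
        assert effective_viscosity_ratio(ef, ViscousParams(gamma)) == pytest.approx(1.0)

    def test_zero_viscosity_rejected(self):
        with pytest.raises(ValueError):
            effective_viscosity_ratio(ElasticFluidParams(), ViscousParams(0.0))
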