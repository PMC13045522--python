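import numpy as np
import pytest

from valvejet.jetting import (
    FluidProperties,
    JetConditions,
    capillary_time,
    characteristic_viscosity,
    dimensionless_numbers,
    invert_dimensionless,
    oh_from_we_re,
    pinch_off_time,
    splash_parameter,
)
from valvejet.rheology import PowerLawFit
from valvejet.units import PhysicalConstants

from conftest import NOZZLE_DIAMETER_M, PRINTED_FROUDE, PRINTED_SPLASH, PRINTED_TRIPLES


class TestOhIdentity:
    @pytest.mark.parametrize("name", sorted(PRINTED_TRIPLES))
    def test_printed_triples(self, name):
        """√We/Re reproduces each fully printed Oh within 1% relative."""
        we, re, oh_printed = PRINTED_TRIPLES[name]
        assert oh_from_we_re(we, re) == pytest.approx(oh_printed, rel=0.01)

    def test_identity_point(self):
        assert oh_from_we_re(1.0, 1.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            oh_from_we_re(-1.0, 1.0)


class TestSplashParameter:
    @pytest.mark.parametrize("name", sorted(PRINTED_SPLASH))
    def test_printed_values(self, name):
        """Oh·Re^1.25 reproduces the reported splash parameters within 5%."""
        oh, re, k_printed = PRINTED_SPLASH[name]
        assert splash_parameter(oh, re) == pytest.approx(k_printed, rel=0.05)

    def test_identity_point(self):
        assert splash_parameter(1.0, 1.0) == 1.0

    def test_strictly_increasing_in_both_arguments(self):
        base = splash_parameter(0.1, 100.0)
        assert splash_parameter(0.2, 100.0) > base
        assert splash_parameter(0.1, 200.0) > base


class TestDimensionlessNumbers:
    FLUID = FluidProperties(density=1000.0, surface_tension=0.0539,
                            characteristic_viscosity=1.00e-3)
    JET = JetConditions(jet_velocity=4.77, nozzle_diameter=2.5e-4)

    def test_forward_matches_backsolved_fibrinogen(self):
        """Properties back-solved from the printed fibrinogen set reproduce it."""
        we, re, _ = PRINTED_TRIPLES["fibrinogen 5 mg/mL"]
        fr = PRINTED_FROUDE["fibrinogen 5 mg/mL"]
        v, sigma, mu = invert_dimensionless(we, re, fr, 1000.0, NOZZLE_DIAMETER_M)
        fluid = FluidProperties(1000.0, sigma, mu)
        jet = JetConditions(jet_velocity=v, nozzle_diameter=NOZZLE_DIAMETER_M)
        nums = dimensionless_numbers(fluid, jet)
        assert nums.weber == pytest.approx(we, rel=1e-9)
        assert nums.reynolds == pytest.approx(re, rel=1e-9)
        assert nums.froude == pytest.approx(fr, rel=1e-9)
        # and the physical scale is right: ~4.8 m/s jet, water-like σ and µ
        assert v == pytest.approx(4.77, rel=0.01)
        assert sigma == pytest.approx(0.054, rel=0.02)
        assert mu == pytest.approx(1.0e-3, rel=0.02)

    def test_velocity_scaling_laws(self):
        a = dimensionless_numbers(self.FLUID, self.JET)
        jet2 = JetConditions(jet_velocity=2 * 4.77, nozzle_diameter=2.5e-4)
        b = dimensionless_numbers(self.FLUID, jet2)
        assert b.weber == pytest.approx(4 * a.weber)
        assert b.reynolds == pytest.approx(2 * a.reynolds)
        assert b.froude == pytest.approx(2 * a.froude)
        assert b.ohnesorge == pytest.approx(a.ohnesorge)

    def test_viscosity_scaling_laws(self):
        a = dimensionless_numbers(self.FLUID, self.JET)
        fluid2 = FluidProperties(1000.0, 0.0539, 2.0e-3)
        b = dimensionless_numbers(fluid2, self.JET)
        assert b.reynolds == pytest.approx(a.reynolds / 2)
        assert b.ohnesorge == pytest.approx(2 * a.ohnesorge)
        assert b.z_number == pytest.approx(a.z_number / 2)
        assert b.weber == pytest.approx(a.weber)
        assert b.froude == pytest.approx(a.froude)

    def test_internal_identities(self):
        nums = dimensionless_numbers(self.FLUID, self.JET)
        assert nums.ohnesorge == pytest.approx(np.sqrt(nums.weber) / nums.reynolds,
                                               rel=1e-12)
        assert nums.z_number * nums.ohnesorge == pytest.approx(1.0, rel=1e-12)
        assert nums.bond == pytest.approx(nums.weber / nums.froude**2, rel=1e-12)

    def test_bond_number_implies_plausible_surface_tension(self):
        """Inverting the fibrinogen row with ρ in [990, 1050] gives σ in [0.03, 0.08]."""
        we, re, _ = PRINTED_TRIPLES["fibrinogen 5 mg/mL"]
        fr = PRINTED_FROUDE["fibrinogen 5 mg/mL"]
        for rho in (990.0, 1020.0, 1050.0):
            _, sigma, _ = invert_dimensionless(we, re, fr, rho, NOZZLE_DIAMETER_M)
            assert 0.03 <= sigma <= 0.08


class TestInversionRoundTrip:
    def test_thousand_random_draws(self):
        """invert ∘ forward = identity within 1e-9 relative on 1000 draws."""
        rng = np.random.default_rng(42)
        g = PhysicalConstants()
        for _ in range(1000):
            rho = rng.uniform(900, 1100)
            sigma = rng.uniform(0.02, 0.08)
            mu = 10 ** rng.uniform(-3.2, 0.0)
            v = rng.uniform(0.5, 10.0)
            D = rng.uniform(1e-4, 5e-4)
            fluid = FluidProperties(rho, sigma, mu)
            jet = JetConditions(jet_velocity=v, nozzle_diameter=D)
            nums = dimensionless_numbers(fluid, jet, g)
            v2, s2, m2 = invert_dimensionless(
                nums.weber, nums.reynolds, nums.froude, rho, D, g
            )
            assert v2 == pytest.approx(v, rel=1e-9)
            assert s2 == pytest.approx(sigma, rel=1e-9)
            assert m2 == pytest.approx(mu, rel=1e-9)


class TestTimescales:
    def test_capillary_time_magnitude(self):
        """ρ=1000, σ=0.07, R=125 µm → τc ≈ 0.17 ms (a few tenths of a ms)."""
        tau = capillary_time(1000.0, 0.07, 1.25e-4)
        assert tau == pytest.approx(1.67e-4, rel=0.01)

    def test_capillary_time_scaling(self):
        tau = capillary_time(1000.0, 0.07, 1.25e-4)
        assert capillary_time(1000.0, 0.07 / 4, 1.25e-4) == pytest.approx(2 * tau)
        assert capillary_time(1000.0, 0.07, 1.25e-5) < tau

    def test_inviscid_limit(self):
        tau = 1.67e-4
        est = pinch_off_time(tau, ohnesorge=1e-12)
        assert est.pinch_off_time == pytest.approx(tau, rel=1e-9)

    def test_viscous_retardation_and_frequency(self):
        est = pinch_off_time(1.67e-4, ohnesorge=0.01, alpha=2.0)
        assert est.pinch_off_time == pytest.approx(1.67e-4 * 1.02, rel=1e-12)
        assert est.max_frequency == pytest.approx(1 / est.pinch_off_time)
        assert est.max_frequency == pytest.approx(5.87e3, rel=0.01)

    def test_alpha_zero_degenerate(self):
        for oh in (0.01, 1.0, 10.0):
            est = pinch_off_time(2e-4, oh, alpha=0.0)
            assert est.max_frequency == pytest.approx(1 / 2e-4)

    def test_pinch_off_never_faster_than_capillary(self):
        for oh in np.geomspace(1e-3, 10, 20):
            assert pinch_off_time(1e-4, oh).pinch_off_time >= 1e-4


def test_characteristic_viscosity_from_fit():
    """µ_c = K·(v/D)^(n−1) at the default jet shear rate."""
    fit = PowerLawFit(consistency_index=0.01, flow_index=0.8)
    jet = JetConditions(jet_velocity=5.0, nozzle_diameter=2.5e-4)
    gdot_c = 5.0 / 2.5e-4
    assert characteristic_viscosity(fit, jet) == pytest.approx(
        0.01 * gdot_c ** (-0.2)
    )
    # Newtonian fit: path-independent
    newt = PowerLawFit(consistency_index=1e-3, flow_index=1.0)
    assert characteristic_viscosity(newt, jet) == pytest.approx(1e-3)
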