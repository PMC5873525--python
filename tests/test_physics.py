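import numpy as np
import pytest
from scipy.optimize import brentq

from pasquant import physics
from pasquant.errors import ConfigurationError
from pasquant.physics import (
    AirEnvironment,
    DepositionSettings,
    GammaModel,
    MaterialProperties,
    aerodynamic_to_projected,
    deposition_velocity,
    diffusion_coefficient,
    gamma_apply,
    gamma_mesh,
    particle_mass,
    projected_to_aerodynamic,
    settling_velocity,
    slip_correction,
)


class TestAirEnvironment:
    def test_nu_consistent_with_mu_over_rho(self, env):
        assert env.kinematic_viscosity == pytest.approx(
            env.dynamic_viscosity / env.air_mass_density, rel=1e-6
        )

    def test_all_properties_positive(self, env):
        for value in (
            env.dynamic_viscosity,
            env.kinematic_viscosity,
            env.mean_free_path,
            env.air_mass_density,
        ):
            assert value > 0

    def test_mean_free_path_reference_value(self):
        env = AirEnvironment(temperature=293.15, pressure=101325.0)
        assert env.mean_free_path == pytest.approx(66.5e-9, rel=1e-12)

    def test_overrides_respected(self):
        env = AirEnvironment(viscosity_override=1.5e-5, mean_free_path_override=70e-9)
        assert env.dynamic_viscosity == 1.5e-5
        assert env.mean_free_path == 70e-9

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            AirEnvironment(temperature=-1.0)


class TestSlipCorrection:
    def test_no_slip_limit(self, env):
        assert slip_correction(1e-2, env) == pytest.approx(1.0, abs=1e-4)

    def test_one_micron_oracle(self, env):
        # direct evaluation of Cc = 1 + (lam/d)(2.514 + 0.8 exp(-0.55 d/lam))
        lam = env.mean_free_path
        d = 1e-6
        expected = 1 + lam / d * (2.514 + 0.8 * np.exp(-0.55 * d / lam))
        assert slip_correction(d, env) == pytest.approx(expected, rel=1e-12)
        assert slip_correction(d, env) == pytest.approx(1.1671, abs=2e-4)

    def test_tenth_micron_oracle(self, env):
        assert slip_correction(0.1e-6, env) == pytest.approx(2.9031, abs=2e-4)

    def test_always_at_least_one(self, env):
        d = np.geomspace(1e-9, 1e-4, 50)
        assert np.all(slip_correction(d, env) >= 1.0)

    def test_rejects_nonpositive(self, env):
        with pytest.raises(ValueError):
            slip_correction(0.0, env)
        with pytest.raises(ValueError):
            slip_correction(-1e-6, env)


class TestSettlingVelocity:
    def test_ten_micron_oracle(self, env):
        # Stokes + slip oracle, cross-checked with textbook order 3e-3 m/s
        d = 10e-6
        expected = (
            1000.0 * d**2 * 9.80665 * slip_correction(d, env) / (18 * env.dynamic_viscosity)
        )
        assert settling_velocity(d, env) == pytest.approx(expected, rel=1e-12)
        assert settling_velocity(d, env) == pytest.approx(3.06e-3, rel=0.01)

    def test_vanishes_for_tiny_particles(self, env):
        assert settling_velocity(1e-9, env) < 1e-8

    def test_quadratic_scaling_no_slip(self, env):
        # doubling da quadruples vt within 1% where slip is negligible
        v1 = settling_velocity(20e-6, env)
        v2 = settling_velocity(40e-6, env)
        assert v2 / v1 == pytest.approx(4.0, rel=0.01)

    def test_strictly_increasing(self, env):
        d = np.geomspace(0.01e-6, 50e-6, 200)
        v = settling_velocity(d, env)
        assert np.all(np.diff(v) > 0)

    def test_warns_above_stokes_range(self, env):
        with pytest.warns(UserWarning, match="Stokes"):
            settling_velocity(200e-6, env)


class TestDiffusionCoefficient:
    def test_one_micron_oracle(self, env):
        # Stokes-Einstein oracle
        d = 1e-6
        expected = (
            physics.BOLTZMANN * env.temperature * slip_correction(d, env)
            / (3 * np.pi * env.dynamic_viscosity * d)
        )
        assert diffusion_coefficient(d, env) == pytest.approx(expected, rel=1e-12)
        assert diffusion_coefficient(d, env) == pytest.approx(2.763e-11, rel=1e-3)

    def test_decreasing_in_diameter(self, env):
        d = np.geomspace(1e-8, 1e-5, 100)
        assert np.all(np.diff(diffusion_coefficient(d, env)) < 0)

    def test_halving_more_than_doubles(self, env):
        # slip correction makes D grow faster than 1/d
        assert diffusion_coefficient(0.5e-6, env) > 2 * diffusion_coefficient(1e-6, env)

    def test_vanishes_at_low_temperature(self):
        # D ~ T at fixed viscosity and mean free path (Stokes-Einstein)
        mu, lam = 1.81e-5, 66.5e-9
        base = AirEnvironment(
            temperature=293.0, viscosity_override=mu, mean_free_path_override=lam
        )
        cold = AirEnvironment(
            temperature=0.293, viscosity_override=mu, mean_free_path_override=lam
        )
        ratio = diffusion_coefficient(1e-6, cold) / diffusion_coefficient(1e-6, base)
        assert ratio == pytest.approx(1e-3, rel=1e-9)


class TestDepositionVelocity:
    def test_settling_dominated_limit(self, env):
        v = deposition_velocity(10e-6, env)
        vt = settling_velocity(10e-6, env)
        assert v == pytest.approx(vt, rel=1e-3)

    def test_diffusion_dominated_limit(self, env):
        settings = DepositionSettings()
        v = deposition_velocity(0.01e-6, env, settings)
        d_over_delta = diffusion_coefficient(0.01e-6, env) / settings.boundary_layer_m
        assert v == pytest.approx(d_over_delta, rel=0.01)

    def test_exceeds_both_limits_on_grid(self, env):
        # inequality of the closed form, brute-forced over 0.01-20 um
        settings = DepositionSettings()
        da = np.geomspace(0.01e-6, 20e-6, 300)
        v = deposition_velocity(da, env, settings)
        vt = settling_velocity(da, env)
        dl = diffusion_coefficient(da, env) / settings.boundary_layer_m
        assert np.all(v >= np.maximum(vt, dl) * (1 - 1e-12))

    def test_diffusion_off_gives_pure_settling(self, env):
        settings = DepositionSettings(include_diffusion=False)
        da = np.geomspace(0.1e-6, 20e-6, 20)
        np.testing.assert_allclose(
            deposition_velocity(da, env, settings), settling_velocity(da, env)
        )


class TestGammaMesh:
    def test_power_law_at_reference_x(self, env):
        # gamma(X = 1e-3) by direct evaluation of the printed power law
        expected = 5.95e-3 * (1e-3) ** -0.439
        assert expected == pytest.approx(0.12346, abs=1e-5)
        da = brentq(
            lambda d: d * settling_velocity(d, env) / env.kinematic_viscosity - 1e-3,
            1e-7,
            9e-5,
        )
        assert gamma_mesh(da, env) == pytest.approx(expected, rel=1e-6)

    def test_crossover_x_for_027(self, env):
        # root of 5.95e-3 X^-0.439 = 0.27, found independently
        x27 = (0.27 / 5.95e-3) ** (1 / -0.439)
        assert x27 == pytest.approx(1.682e-4, rel=1e-3)
        da = brentq(
            lambda d: d * settling_velocity(d, env) / env.kinematic_viscosity - x27,
            1e-7,
            9e-5,
        )
        assert gamma_mesh(da, env) == pytest.approx(0.27, rel=1e-6)

    def test_tenfold_x_scaling(self, env):
        # X down tenfold -> gamma up by 10**0.439
        g1 = 5.95e-3 * (1e-3) ** -0.439
        g2 = 5.95e-3 * (1e-4) ** -0.439
        assert g2 / g1 == pytest.approx(10**0.439, rel=1e-12)

    def test_strictly_decreasing(self, env):
        da = np.geomspace(0.1e-6, 50e-6, 300)
        assert np.all(np.diff(gamma_mesh(da, env)) < 0)


class TestGammaApply:
    def test_hybrid_caps_at_open_area(self, env):
        # small da: gamma_mesh >= 0.27, so the hybrid returns the cap
        assert gamma_mesh(0.5e-6, env) > 0.27
        assert gamma_apply(0.5e-6, env, GammaModel("hybrid")) == 0.27

    def test_area_constant_everywhere(self, env):
        da = np.geomspace(0.01e-6, 50e-6, 100)
        np.testing.assert_array_equal(gamma_apply(da, env, GammaModel("area")), 0.27)

    def test_hybrid_follows_mesh_below_cap(self, env):
        da = 30e-6  # large: mesh factor below 0.27
        gm = gamma_mesh(da, env)
        assert gm < 0.27
        assert gamma_apply(da, env, GammaModel("hybrid")) == pytest.approx(gm, rel=1e-12)

    def test_hybrid_is_pointwise_min(self, env):
        da = np.geomspace(0.05e-6, 50e-6, 1000)
        hybrid = gamma_apply(da, env, GammaModel("hybrid"))
        mesh = gamma_apply(da, env, GammaModel("mesh"))
        np.testing.assert_array_equal(hybrid, np.minimum(mesh, 0.27))

    def test_hybrid_never_exceeds_area(self, env):
        da = np.geomspace(0.05e-6, 50e-6, 500)
        hybrid = gamma_apply(da, env, GammaModel("hybrid"))
        area = gamma_apply(da, env, GammaModel("area"))
        assert np.all(hybrid <= area)
        equal = hybrid == area
        np.testing.assert_array_equal(equal, gamma_mesh(da, env) >= 0.27)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            GammaModel("wind_tunnel")

    def test_open_area_ratio_bounds(self):
        with pytest.raises(ConfigurationError):
            GammaModel("area", open_area_ratio=0.0)
        with pytest.raises(ConfigurationError):
            GammaModel("area", open_area_ratio=1.5)


class TestDiameterConversions:
    def test_identity_configuration(self, env, identity_material):
        da = projected_to_aerodynamic(1.0, identity_material, env)
        assert da == pytest.approx(1.0, abs=1e-6)

    def test_no_slip_closed_form(self, env, material):
        # d_ve = 1.6**(-1/3), da = d_ve * sqrt(2.8/1.4) = d_ve * sqrt(2)
        da = projected_to_aerodynamic(1.0, material, env, slip=False)
        assert da == pytest.approx(1.6 ** (-1 / 3) * np.sqrt(2.0), rel=1e-12)
        assert da == pytest.approx(1.209, abs=1e-3)

    def test_monotone_in_density(self, env):
        d_pa = 2.0
        das = [
            projected_to_aerodynamic(
                d_pa, MaterialProperties(rho, 1.6, 1.4), env
            )
            for rho in np.linspace(0.5, 5.0, 12)
        ]
        assert np.all(np.diff(das) > 0)

    def test_inverse_round_trip(self, env, material):
        d_pa = np.geomspace(0.1, 50, 40)
        da = projected_to_aerodynamic(d_pa, material, env)
        back = aerodynamic_to_projected(da, material, env)
        np.testing.assert_allclose(back, d_pa, atol=1e-5)

    def test_slip_solution_satisfies_defining_equation(self, env, material):
        d_pa = 1.0
        da = projected_to_aerodynamic(d_pa, material, env)
        d_ve = d_pa * material.volume_shape_factor ** (-1 / 3)
        lhs = da**2 * slip_correction(da * 1e-6, env) * 1000.0
        rhs = (
            d_ve**2
            * slip_correction(d_ve * 1e-6, env)
            * material.density_kg_m3
            / material.dynamic_shape_factor
        )
        assert lhs == pytest.approx(rhs, rel=1e-5)


class TestParticleMass:
    def test_unit_sphere(self, identity_material):
        assert particle_mass(1.0, identity_material) == pytest.approx(np.pi / 6, rel=1e-12)
        assert particle_mass(1.0, identity_material) == pytest.approx(0.5236, abs=1e-4)

    def test_shape_factor_linearity(self):
        m1 = particle_mass(1.0, MaterialProperties(1.0, 1.0, 1.0))
        m2 = particle_mass(1.0, MaterialProperties(1.0, 1.6, 1.0))
        assert m2 == pytest.approx(m1 / 1.6, rel=1e-12)

    def test_cubic_scaling(self, material):
        assert particle_mass(2.0, material) == pytest.approx(
            8 * particle_mass(1.0, material), rel=1e-12
        )
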