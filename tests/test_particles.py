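"""Material database, core/shell geometry, and the three particle forces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdtsim.constants import KB, MU0
from mdtsim.particles import (MATERIALS, Material, ParticleSpec,
                              brownian_force, clausius_mossotti,
                              diffusion_coefficient, drag_force,
                              magnetophoretic_force, register_material,
                              relaxation_time)
from mdtsim.particles import brownian_amplitude


def test_shipped_material_database():
    assert MATERIALS["Fe3O4"].susceptibility == 3.1
    assert MATERIALS["Fe3O4"].density == 5230
    assert MATERIALS["Fe2O3"].susceptibility == 2.5
    assert MATERIALS["Fe2O3"].density == 4890
    assert MATERIALS["Fe"].susceptibility == 3.9
    assert MATERIALS["Fe"].density == 7760
    assert MATERIALS["blood"].density == 1060
    assert MATERIALS["blood"].viscosity == 0.0035
    assert MATERIALS["blood"].susceptibility == -6.6e-7
    assert MATERIALS["Au"].density == 19320
    assert MATERIALS["SiO2"].density == 2648
    assert MATERIALS["PEG"].density == 1114
    for coat in ("Au", "SiO2", "PEG"):
        assert MATERIALS[coat].susceptibility == 0.0


def test_register_material():
    register_material(Material("testium", density=1000.0), overwrite=True)
    assert MATERIALS["testium"].density == 1000.0
    with pytest.raises(ValueError):
        register_material(Material("testium", density=1.0))
    del MATERIALS["testium"]


class TestParticleSpec:
    def test_core_shell_geometry(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9,
                         shell=MATERIALS["Au"], shell_thickness=10e-9)
        assert s.diameter == pytest.approx(120e-9)
        assert s.hydrodynamic_radius == pytest.approx(60e-9)
        v_tot = 4 / 3 * math.pi * (60e-9) ** 3
        v_core = 4 / 3 * math.pi * (50e-9) ** 3
        assert s.mass == pytest.approx(
            5230 * v_core + 19320 * (v_tot - v_core))
        assert s.effective_density == pytest.approx(s.mass / v_tot)

    def test_bare_core_effective_density_exact(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        assert s.effective_density == 5230.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=-1e-9)
        with pytest.raises(ValueError):
            ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=1e-9,
                         shell_thickness=1e-9)


class TestClausiusMossotti:
    def test_identical_media_gives_zero(self):
        assert clausius_mossotti(0.5, 0.5) == 0.0

    @pytest.mark.parametrize("chi_p, expected", [
        (3.1, 0.5082), (3.9, 0.5652), (2.5, 0.4545)])
    def test_core_materials_in_blood(self, chi_p, expected):
        assert clausius_mossotti(chi_p, -6.6e-7) == pytest.approx(expected,
                                                                  abs=2e-4)

    @given(st.floats(min_value=-0.99, max_value=1e4),
           st.floats(min_value=-0.99, max_value=1e4))
    @settings(max_examples=200, deadline=None)
    def test_bounded(self, chi_p, chi_b):
        assert -0.5 <= clausius_mossotti(chi_p, chi_b) <= 1.0

    def test_rejects_unphysical(self):
        with pytest.raises(ValueError):
            clausius_mossotti(-1.5, 0.0)


class TestMagnetophoreticForce:
    def test_zero_in_uniform_field(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=100e-9)
        f = magnetophoretic_force(s, [0.0, 0.0])
        assert f.magnitude == 0.0
        assert f.kind == "magnetophoretic"

    def test_cubic_scaling_with_core_radius(self):
        g = [1e10, -3e10]
        f1 = magnetophoretic_force(
            ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=1e-7), g)
        f2 = magnetophoretic_force(
            ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=2e-7), g)
        assert f2.magnitude == pytest.approx(8 * f1.magnitude, rel=1e-12)

    def test_paper_scale_example(self):
        # |H| = 0.5 T / mu0, |grad H| = 180 T/m / mu0, 2 um Fe3O4 core
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=2e-6)
        grad_h2 = 2 * (0.5 / MU0) * (180.0 / MU0)
        f = magnetophoretic_force(s, [0.0, -grad_h2])
        oracle = (2 * math.pi * MU0 * (1 - 6.6e-7) * (2e-6) ** 3
                  * 0.5082 * grad_h2)
        assert f.magnitude == pytest.approx(oracle, rel=1e-4)
        assert f.magnitude == pytest.approx(3.7e-9, rel=0.02)

    def test_shell_does_not_change_force(self):
        g = [2e9, 5e9]
        bare = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        coated = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9,
                              shell=MATERIALS["PEG"], shell_thickness=50e-9)
        assert np.array_equal(magnetophoretic_force(bare, g).vector,
                              magnetophoretic_force(coated, g).vector)


class TestDragAndRelaxation:
    def test_relaxation_time_hundred_nm(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        tau = relaxation_time(s, 0.0035)
        assert tau == pytest.approx(5230 * (100e-9) ** 2 / (18 * 0.0035),
                                    rel=1e-12)
        assert tau == pytest.approx(8.3e-10, rel=0.01)

    def test_quadratic_scaling_with_diameter(self):
        s1 = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        s2 = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=100e-9)
        assert relaxation_time(s2, 0.0035) == pytest.approx(
            4 * relaxation_time(s1, 0.0035), rel=1e-12)

    def test_zero_slip_zero_force(self):
        s = ParticleSpec(core=MATERIALS["Fe"], core_radius=80e-9)
        u = np.array([0.1, -0.05])
        assert drag_force(s, u, u, 0.0035).magnitude == 0.0

    @given(st.floats(min_value=-8, max_value=-6.3),
           st.floats(min_value=0, max_value=50e-9),
           st.integers(min_value=0, max_value=2))
    @settings(max_examples=50, deadline=None)
    def test_stokes_identity(self, log_r, thick, mat_i):
        """m_p / tau_p == 3 pi eta D for any core/shell composition."""
        r = 10.0 ** log_r
        shell = [None, MATERIALS["Au"], MATERIALS["PEG"]][mat_i]
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=r,
                         shell=shell, shell_thickness=thick if shell else 0.0)
        ub = np.array([0.03, 0.01])
        up = np.array([-0.01, 0.02])
        f = drag_force(s, ub, up, 0.0035).vector
        oracle = 3 * math.pi * 0.0035 * s.diameter * (ub - up)
        np.testing.assert_allclose(f, oracle, rtol=1e-12)

    def test_direction_opposes_slip(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        ub = np.array([0.1, 0.0])
        up = np.array([0.2, 0.05])
        f = drag_force(s, ub, up, 0.0035).vector
        assert float(f @ (up - ub)) < 0


class TestBrownianForce:
    def test_amplitude_value(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        amp = brownian_amplitude(s, 0.0035, 310.0, 1e-4)
        oracle = math.sqrt(12 * math.pi * 50e-9 * 0.0035 * KB * 310 / 1e-4)
        assert amp == pytest.approx(oracle, rel=1e-12)
        assert amp == pytest.approx(5.3e-13, rel=0.01)

    def test_zero_mean(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        g = np.random.default_rng(0)
        samples = np.array([brownian_force(s, 0.0035, 310.0, 1e-4, g).vector
                            for _ in range(10 ** 4)])
        amp = brownian_amplitude(s, 0.0035, 310.0, 1e-4)
        se = amp / math.sqrt(len(samples))
        assert np.all(np.abs(samples.mean(axis=0)) < 4 * se)

    def test_amplitude_independent_of_density_and_field(self):
        light = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        heavy = ParticleSpec(core=MATERIALS["Fe"], core_radius=50e-9)
        assert (brownian_amplitude(light, 0.0035, 310.0, 1e-4)
                == brownian_amplitude(heavy, 0.0035, 310.0, 1e-4))

    def test_rejects_bad_arguments(self):
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        with pytest.raises(ValueError):
            brownian_amplitude(s, 0.0035, -1.0, 1e-4)
        with pytest.raises(ValueError):
            brownian_amplitude(s, 0.0035, 310.0, 0.0)

    def test_free_diffusion_recovers_einstein_msd(self):
        """Overdamped displacements driven by the Brownian force amplitude
        reproduce MSD(t) = 2 D t per dimension within 5%."""
        s = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        eta, T, dt, n_steps, n_part = 0.0035, 310.0, 1e-4, 500, 10 ** 4
        amp = brownian_amplitude(s, eta, T, dt)
        mobility = 1.0 / (3 * math.pi * eta * s.diameter)
        g = np.random.default_rng(42)
        # x += F_B * mobility * dt, per dimension
        steps = g.standard_normal((n_steps, n_part)) * amp * mobility * dt
        x = steps.sum(axis=0)
        msd = float(np.mean(x ** 2))
        d_coef = diffusion_coefficient(s, eta, T)
        assert msd == pytest.approx(2 * d_coef * n_steps * dt, rel=0.05)
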