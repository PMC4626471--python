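"""Trajectory integration, wall/capture rules, bookkeeping, and sweeps."""

from dataclasses import replace

import numpy as np
import pytest

from mdtsim.particles import MATERIALS, Material, ParticleSpec
from mdtsim.transport import (CaptureResult, ParticleState, SimulationConfig,
                              TransportEnv, capture_efficiency, inject, run,
                              step, sweep_coating, sweep_core_size,
                              wall_interaction)


@pytest.fixture(scope="module")
def small_config(calibrated_magnet):
    return SimulationConfig(magnet=calibrated_magnet, n_particles=60,
                            t_max=0.8, seed=3)


@pytest.fixture(scope="module")
def quiet_env(calibrated_magnet):
    """Plug flow, magnet off, Brownian off: pure advection."""
    cfg = SimulationConfig(magnet=replace(calibrated_magnet, b_rem=0.0),
                           n_particles=1, brownian=False, profile_mode="plug")
    return TransportEnv(cfg)


class TestCaptureEfficiency:
    def test_paper_worked_example(self):
        assert round(capture_efficiency(3251, 3191), 2) == 1.85

    def test_limits(self):
        assert capture_efficiency(100, 100) == 0.0
        assert capture_efficiency(100, 0) == 100.0

    def test_undefined_for_no_entries(self):
        with pytest.raises(ValueError):
            capture_efficiency(0, 0)
        with pytest.raises(ValueError):
            capture_efficiency(10, 11)


class TestInject:
    def test_even_split_across_bursts(self, small_config):
        states = inject(small_config)
        t_counts = {}
        for s in states:
            t_counts[s.injection_time] = t_counts.get(s.injection_time, 0) + 1
        assert t_counts == {t: 10 for t in small_config.injection_times}

    def test_positions_exclude_wall_layer(self, small_config):
        r_h = small_config.particle.hydrodynamic_radius
        w = small_config.geometry.width
        for s in inject(small_config):
            assert r_h < s.position[1] < w - r_h

    def test_deterministic(self, small_config):
        a = inject(small_config)
        b = inject(small_config)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.position, s2.position)
            assert np.array_equal(s1.velocity, s2.velocity)

    def test_noise_streams_stable_under_count_change(self, small_config):
        few = inject(replace(small_config, n_particles=12))
        many = inject(replace(small_config, n_particles=60))
        for s1, s2 in zip(few, many):
            assert np.array_equal(s1.position, s2.position)


class TestStep:
    def test_equilibrium_advection(self, quiet_env):
        """A force-free particle moving with the fluid is advected exactly."""
        vm = quiet_env.waveform(0.2)
        s = ParticleState(position=np.array([0.005, 0.002]),
                          velocity=np.array([vm, 0.0]))
        s2 = step(s, 0.2, 1e-4, quiet_env)
        np.testing.assert_allclose(s2.velocity, [vm, 0.0], rtol=1e-12)
        np.testing.assert_allclose(
            s2.position, [0.005 + vm * 1e-4, 0.002], rtol=1e-12)

    def test_inertial_terminal_velocity_one_step(self, calibrated_magnet):
        """With tau_p << dt the exponential integrator lands on the terminal
        slip velocity u_b + F/(3 pi eta D) after a single step."""
        cfg = SimulationConfig(magnet=calibrated_magnet, brownian=False,
                               integrator="inertial", profile_mode="plug")
        env = TransportEnv(cfg)
        pos = np.array([0.02, 0.002])
        s = ParticleState(position=pos, velocity=np.array([0.0, 0.0]))
        s2 = step(s, 0.0, 1e-4, env)
        ubx, _ = env.blood_velocity(pos[:1], pos[1:], 0.0)
        mdx, mdy = env.magnetic_drift(pos[:1], pos[1:], env.eta_const)
        expected = np.array([ubx[0] + mdx[0], mdy[0]])
        np.testing.assert_allclose(s2.velocity, expected, rtol=1e-6)

    def test_overdamped_matches_inertial_trajectory(self, calibrated_magnet):
        """tau_p/dt ~ 1e-5: both integrators give the same path to < 1 nm."""
        base = SimulationConfig(magnet=calibrated_magnet, brownian=False)
        paths = {}
        for integ in ("overdamped", "inertial"):
            cfg = replace(base, integrator=integ)
            env = TransportEnv(cfg)
            s = ParticleState(position=np.array([0.005, 0.0015]),
                              velocity=np.array([0.0, 0.0]))
            traj = []
            for k in range(1000):
                s = step(s, k * 1e-4, 1e-4, env)
                traj.append(s.position.copy())
            paths[integ] = np.asarray(traj)
        gap = np.max(np.abs(paths["overdamped"] - paths["inertial"]))
        assert gap < 1e-9

    def test_only_flowing_particles_step(self, quiet_env):
        s = ParticleState(position=np.array([0.005, 0.002]),
                          velocity=np.zeros(2), status="captured")
        with pytest.raises(ValueError):
            step(s, 0.0, 1e-4, quiet_env)


class TestWallInteraction:
    def test_reflection_preserves_speed(self, calibrated_magnet):
        geom = SimulationConfig().geometry
        spec = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        # contact outside the footprint -> always reflects
        s = ParticleState(position=np.array([0.005, 1e-9]),
                          velocity=np.array([0.08, -0.02]))
        s2 = wall_interaction(s, geom, calibrated_magnet, spec)
        assert s2.status == "flowing"
        assert np.hypot(*s2.velocity) == pytest.approx(np.hypot(*s.velocity),
                                                       rel=1e-12)
        assert s2.velocity[1] == -s.velocity[1]

    def test_capture_at_near_wall_in_footprint(self, calibrated_magnet):
        geom = SimulationConfig().geometry
        spec = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        s = ParticleState(position=np.array([0.02, 1e-9]),
                          velocity=np.array([0.08, -0.02]))
        s2 = wall_interaction(s, geom, calibrated_magnet, spec)
        assert s2.status == "captured"
        assert s2.position[1] == spec.hydrodynamic_radius

    def test_no_capture_with_magnet_off(self, calibrated_magnet):
        geom = SimulationConfig().geometry
        spec = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        off = replace(calibrated_magnet, b_rem=0.0)
        s = ParticleState(position=np.array([0.02, 1e-9]),
                          velocity=np.array([0.08, -0.02]))
        assert wall_interaction(s, geom, off, spec).status == "flowing"

    def test_untouched_when_clear_of_walls(self, calibrated_magnet):
        geom = SimulationConfig().geometry
        spec = ParticleSpec(core=MATERIALS["Fe3O4"], core_radius=50e-9)
        s = ParticleState(position=np.array([0.02, 0.002]),
                          velocity=np.array([0.08, 0.0]))
        assert wall_interaction(s, geom, calibrated_magnet, spec) is s


class TestRun:
    def test_magnet_off_null_efficiency(self, small_config):
        res = run(replace(small_config,
                          magnet=replace(small_config.magnet, b_rem=0.0)))
        assert res.n_captured == 0
        assert res.efficiency_pct == 0.0

    def test_repulsive_core_never_captured_at_near_wall(self, small_config):
        """chi_p < chi_b reverses the force: it points away from the magnet,
        so no contact on the approach side can satisfy the capture rule."""
        repulsive = Material("diacore", density=5230.0,
                             susceptibility=-1e-4)
        cfg = replace(small_config, brownian=False,
                      particle=ParticleSpec(core=repulsive,
                                            core_radius=50e-9))
        res = run(cfg)
        assert res.n_captured == 0
        assert res.efficiency_pct == 0.0

    def test_replay_bit_identical(self, small_config):
        assert run(small_config) == run(small_config)

    def test_count_conservation(self, small_config):
        res = run(small_config)
        assert res.eps_in == (res.eps_out + res.n_captured
                              + res.n_flowing_at_tmax)
        # constructing an inconsistent result is rejected outright
        with pytest.raises(ValueError):
            CaptureResult(eps_in=10, eps_out=5, n_captured=2,
                          n_flowing_at_tmax=1, seed=0, n_injected=10)

    def test_particle_reynolds_guard_monitored(self, small_config):
        res = run(small_config)
        assert res.re_p_max < 1.0
        assert res.re_p_violations == 0

    def test_trajectory_recording(self, small_config):
        cfg = replace(small_config, n_particles=12, t_max=0.2)
        res, frame = run(cfg, record_stride=50)
        assert {"t", "particle", "x", "y", "vx", "vy"} <= set(frame.columns)
        assert len(frame) > 0
        assert frame["y"].between(0, cfg.geometry.width).all()


class TestSweeps:
    def test_single_radius_matches_direct_run(self, small_config):
        tab = sweep_core_size(small_config, [100e-9])
        from mdtsim.transport import _child_seed

        direct = run(replace(
            small_config, seed=_child_seed(small_config.seed, 0),
            particle=replace(small_config.particle, core_radius=100e-9)))
        assert len(tab) == 1
        assert tab.loc[0, "captured"] == direct.n_captured
        assert tab.loc[0, "efficiency_pct"] == direct.efficiency_pct

    def test_radius_range_enforced(self, small_config):
        with pytest.raises(ValueError):
            sweep_core_size(small_config, [5e-9])

    def test_zero_thickness_equals_bare(self, small_config):
        tab = sweep_coating(small_config, [("Au", 0.0)])
        bare = tab[tab["material"] == "bare"].iloc[0]
        coated = tab[tab["material"] == "Au"].iloc[0]
        assert coated["captured"] == bare["captured"]
        assert coated["efficiency_pct"] == bare["efficiency_pct"]

    def test_one_row_per_requested_pair(self, small_config):
        pairs = [(m, t) for m in ("Au", "SiO2", "PEG")
                 for t in (5e-9, 50e-9)]
        cfg = replace(small_config, n_particles=12, t_max=0.2)
        tab = sweep_coating(cfg, pairs)
        assert len(tab) == len(pairs) + 1   # + bare baseline
        got = set(zip(tab["material"], tab["thickness_m"]))
        assert got == set((m, t) for m, t in pairs) | {("bare", 0.0)}
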