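"""Lagrangian transport of magnetic carriers through the pulsatile channel.

Particles are injected as plug flow at the inlet in six bursts, advected by
the quasi-steady blood profile, driven toward the wall by the magnetophoretic
force, dispersed by Brownian noise, and resolved against the wall rule:
contact inside the magnet footprint with a wall-directed magnetic force means
capture (position frozen), any other contact is a specular elastic reflection.

Two integrators satisfy the particle equation of motion
m_p r'' = F_M + F_D + F_B:

* ``overdamped`` (default): the momentum relaxation time of a nanoparticle in
  blood is nanoseconds, far below any practical time step, so the particle
  velocity is slaved to u_b + F_M/(3 pi eta D) and the Brownian force enters
  as its exact overdamped displacement sqrt(2 D_diff dt).
* ``inertial``: exponential integrator for the linear drag term (factor
  exp(-dt/tau_p), forces frozen over the step); unconditionally stable and
  exact for constant force.

Capture efficiency follows eps = (eps_in - eps_out) / eps_in x 100 with
eps_in the particles entering the magnet-footprint section and eps_out those
leaving it downstream; particles still unresolved at t_max are excluded from
the denominator and reported separately.

Every particle consumes an independent, reproducible noise stream spawned
from the master seed, so runs replay bit-identically and changing the
particle count does not reshuffle the noise of existing particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .constants import BODY_TEMPERATURE, KB, MU0
from .hemodynamics import (ChannelGeometry, DevelopedProfileTable,
                           FlowWaveform, ViscosityParams, apparent_viscosity,
                           make_waveform, mean_velocity)
from .magnetics import MagnetSpec, _grad_h2
from .particles import MATERIALS, ParticleSpec, clausius_mossotti

__all__ = [
    "SimulationConfig",
    "ParticleState",
    "CaptureResult",
    "TransportEnv",
    "inject",
    "step",
    "wall_interaction",
    "run",
    "capture_efficiency",
    "sweep_core_size",
    "sweep_coating",
]

_STATUS = {"flowing": 0, "captured": 1, "exited": 2, "washed_out": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one capture-efficiency run."""

    geometry: ChannelGeometry = ChannelGeometry()
    magnet: MagnetSpec = MagnetSpec(
        b_rem=2.0, center=(0.02, -0.02), width=0.0036, height=0.020)
    waveform: FlowWaveform | None = None   # None -> default landmark waveform
    viscosity: ViscosityParams = ViscosityParams()
    particle: ParticleSpec = ParticleSpec(
        core=MATERIALS["Fe3O4"], core_radius=50e-9)
    n_particles: int = 6000
    injection_times: tuple[float, ...] = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)
    dt: float = 1e-4
    t_max: float = 5.0
    temperature: float = BODY_TEMPERATURE
    seed: int = 0
    integrator: Literal["overdamped", "inertial"] = "overdamped"
    brownian: bool = True
    chi_blood: float = -6.6e-7
    profile_mode: Literal["mixed", "plug", "developed"] = "mixed"
    particle_viscosity: Literal["constant", "local"] = "constant"
    mean_inlet_velocity: float = 0.10

    def __post_init__(self):
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(t >= self.t_max for t in self.injection_times):
            raise ValueError("injection times must precede t_max")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def resolved_waveform(self) -> FlowWaveform:
        if self.waveform is not None:
            return self.waveform
        return make_waveform(mean=self.mean_inlet_velocity)


@dataclass
class ParticleState:
    """One carrier's kinematic state."""

    position: np.ndarray
    velocity: np.ndarray
    status: str = "flowing"
    injection_time: float = 0.0
    event_time: float | None = None   # capture or exit time


@dataclass(frozen=True)
class CaptureResult:
    """Capture bookkeeping for the magnet-footprint section of the vessel.

    ``n_flowing_at_tmax`` counts particles that entered the section but were
    still unresolved when the clock ran out (including the rare ones washed
    back out of the inlet); they are excluded from the efficiency
    denominator.
    """

    eps_in: int
    eps_out: int
    n_captured: int
    n_flowing_at_tmax: int
    seed: int
    n_injected: int
    re_p_max: float = 0.0
    re_p_violations: int = 0

    def __post_init__(self):
        if self.eps_in != (self.eps_out + self.n_captured
                           + self.n_flowing_at_tmax):
            raise ValueError("particle count bookkeeping is inconsistent")

    @property
    def efficiency_pct(self) -> float:
        resolved = self.eps_out + self.n_captured
        if resolved == 0:
            return 0.0
        return capture_efficiency(resolved, self.eps_out)

    @property
    def stderr_pct(self) -> float:
        """Binomial Monte Carlo standard error of the efficiency, %."""
        n = self.eps_out + self.n_captured
        if n == 0:
            return 0.0
        p = self.n_captured / n
        return 100.0 * math.sqrt(p * (1.0 - p) / n)


def capture_efficiency(eps_in: int, eps_out: int) -> float:
    """Capture efficiency (eps_in - eps_out) / eps_in x 100, percent."""
    if eps_in <= 0:
        raise ValueError("undefined efficiency: no particles entered")
    if not 0 <= eps_out <= eps_in:
        raise ValueError("eps_out must lie in [0, eps_in]")
    return (eps_in - eps_out) / eps_in * 100.0


class _NoiseStreams:
    """Per-particle PCG64 substreams with buffered block draws."""

    CHUNK = 256

    def __init__(self, seed: int, n: int):
        self._children = np.random.SeedSequence(seed).spawn(n)
        self._gens: list[np.random.Generator | None] = [None] * n
        self._buf = np.zeros((n, self.CHUNK, 2))
        self._ptr = np.full(n, self.CHUNK, dtype=np.int64)

    def generator(self, i: int) -> np.random.Generator:
        g = self._gens[i]
        if g is None:
            g = np.random.Generator(np.random.PCG64(self._children[i]))
            self._gens[i] = g
        return g

    def normals(self, idx: np.ndarray) -> np.ndarray:
        need = idx[self._ptr[idx] >= self.CHUNK]
        for i in need:
            self._buf[i] = self.generator(int(i)).standard_normal(
                (self.CHUNK, 2))
            self._ptr[i] = 0
        z = self._buf[idx, self._ptr[idx], :]
        self._ptr[idx] += 1
        return z


_PROFILE_CACHE: dict[tuple, DevelopedProfileTable] = {}


def _profile_table(geom: ChannelGeometry, visc: ViscosityParams,
                   v_max: float) -> DevelopedProfileTable:
    key = (geom.width, round(v_max, 6), visc)
    tab = _PROFILE_CACHE.get(key)
    if tab is None:
        tab = DevelopedProfileTable(geom.width, v_max, visc)
        _PROFILE_CACHE[key] = tab
    return tab


class TransportEnv:
    """Precomputed per-run environment: field, flow table, particle constants."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.geom = config.geometry
        self.magnet = config.magnet
        self.waveform = config.resolved_waveform()
        self.visc = config.viscosity
        spec = config.particle

        self._check_magnet_outside()

        tt = np.linspace(0.0, self.waveform.period, 2001)
        v_max = float(np.max(np.abs(self.waveform(tt)))) * 1.05
        self.profile = _profile_table(self.geom, self.visc, v_max)

        self.r_h = spec.hydrodynamic_radius
        self.diameter = spec.diameter
        self.mass = spec.mass
        self.rho_eff = spec.effective_density
        self.eta_const = MATERIALS["blood"].viscosity
        K = clausius_mossotti(spec.core.susceptibility, config.chi_blood)
        self.mu_b = MU0 * (1.0 + config.chi_blood)
        #: F_M = coeff_fm * grad|H|^2
        self.coeff_fm = 2.0 * math.pi * self.mu_b * spec.core_radius ** 3 * K

    def _check_magnet_outside(self):
        g = self.geom
        m = self.magnet
        corners = [(x, y) for x in (0.0, g.length) for y in (0.0, g.width)]
        if any(m.contains(c) for c in corners) or m.contains(
                (g.length / 2, g.width / 2)):
            raise ValueError("magnet body overlaps the channel")
        F = m._frame
        cx = np.clip(np.array([0.0, g.length]), None, None)
        # sample channel boundary densely for overlap
        xs = np.linspace(0.0, g.length, 101)
        for y in (0.0, g.width):
            if any(m.contains((x, y)) for x in xs):
                raise ValueError("magnet body overlaps the channel")

    # --- local flow and viscosity -----------------------------------------
    def blood_velocity(self, x, y, t):
        """(u_x, u_y) of the blood at particle positions; u_y = 0."""
        vm = mean_velocity(t, self.waveform)
        mode = self.config.profile_mode
        if mode == "plug":
            ux = np.full_like(np.asarray(x, dtype=float), vm)
        elif mode == "developed":
            ux = np.where(x >= 0.0, self.profile.u(y, vm), vm)
        else:
            f0, f1 = self.geom.magnet_footprint
            in_foot = (x >= f0) & (x <= f1)
            ux = np.where(in_foot, self.profile.u(y, vm), vm)
        return ux, np.zeros_like(ux)

    def local_viscosity(self, x, y, t):
        if self.config.particle_viscosity == "constant":
            return self.eta_const
        vm = mean_velocity(t, self.waveform)
        mode = self.config.profile_mode
        if mode == "plug":
            gd = np.zeros_like(np.asarray(x, dtype=float))
        elif mode == "developed":
            gd = self.profile.shear(y, vm)
        else:
            f0, f1 = self.geom.magnet_footprint
            in_foot = (x >= f0) & (x <= f1)
            gd = np.where(in_foot, self.profile.shear(y, vm), 0.0)
        return apparent_viscosity(gd, self.visc)

    def grad_h2(self, x, y):
        gx, gy = _grad_h2(self.magnet, x, y)
        return gx, gy

    def magnetic_drift(self, x, y, eta):
        """F_M / (3 pi eta D): the terminal magnetophoretic slip velocity."""
        gx, gy = self.grad_h2(x, y)
        c = self.coeff_fm / (3.0 * math.pi * eta * self.diameter)
        return c * gx, c * gy

    def tau_p(self, eta):
        return self.rho_eff * self.diameter ** 2 / (18.0 * eta)

    def diffusivity(self, eta):
        return KB * self.config.temperature / (
            6.0 * math.pi * eta * self.r_h)


def inject(config: SimulationConfig,
           rng: np.random.Generator | None = None) -> list[ParticleState]:
    """Initial states: N particles split evenly across the injection bursts.

    Transverse positions are uniform over the inlet excluding one
    hydrodynamic radius from each wall; the initial velocity is the plug
    inlet velocity at the burst time.  When ``rng`` is omitted the
    per-particle substreams of the master seed are used, which is what
    :func:`run` replays.
    """
    t_inj, y0 = _injection_arrays(config, rng)
    w = config.resolved_waveform()
    states = []
    for i in range(config.n_particles):
        v0 = mean_velocity(t_inj[i], w)
        states.append(ParticleState(
            position=np.array([0.0, y0[i]]),
            velocity=np.array([v0, 0.0]),
            injection_time=float(t_inj[i])))
    return states


def _injection_arrays(config: SimulationConfig,
                      rng: np.random.Generator | None = None):
    n = config.n_particles
    times = np.asarray(config.injection_times)
    t_inj = times[np.arange(n) % len(times)]
    r_h = config.particle.hydrodynamic_radius
    w = config.geometry.width
    if w <= 2 * r_h:
        raise ValueError("particle does not fit in the channel")
    if rng is not None:
        y0 = rng.uniform(r_h, w - r_h, n)
    else:
        streams = _NoiseStreams(config.seed, n)
        y0 = np.array([streams.generator(i).uniform(r_h, w - r_h)
                       for i in range(n)])
    return t_inj, y0


def _capture_mask(env: TransportEnv, x, y, at_bottom):
    """Capture predicate at wall-contact points: inside the footprint and
    the wall-normal magnetophoretic force strictly into the wall."""
    f0, f1 = env.geom.magnet_footprint
    in_foot = (x >= f0) & (x <= f1)
    _, gy = env.grad_h2(x, y)
    fy = env.coeff_fm * gy
    toward_wall = np.where(at_bottom, fy < 0.0, fy > 0.0)
    return in_foot & toward_wall


def wall_interaction(state: ParticleState, geom: ChannelGeometry,
                     magnet: MagnetSpec, spec: ParticleSpec,
                     chi_blood: float = -6.6e-7) -> ParticleState:
    """Resolve a wall contact for a single particle.

    Capture freezes the particle at the contact point; otherwise the
    position is mirrored about the contact plane and the wall-normal
    velocity negated (specular elastic reflection).
    """
    r_h = spec.hydrodynamic_radius
    x, y = state.position
    if r_h <= y <= geom.width - r_h:
        return state
    at_bottom = y < r_h
    y_c = r_h if at_bottom else geom.width - r_h
    cfg = SimulationConfig(geometry=geom, magnet=magnet, particle=spec,
                           chi_blood=chi_blood)
    env = TransportEnv(cfg)
    cap = _capture_mask(env, np.asarray([x]), np.asarray([y_c]),
                        np.asarray([at_bottom]))[0]
    if cap:
        return replace(state, position=np.array([x, y_c]), status="captured",
                       velocity=np.zeros(2))
    y_new = 2.0 * y_c - y
    y_new = min(max(y_new, r_h), geom.width - r_h)
    return replace(state, position=np.array([x, y_new]),
                   velocity=state.velocity * np.array([1.0, -1.0]))


class _Engine:
    """Vectorized stepper over all injected particles."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.env = TransportEnv(config)
        n = config.n_particles
        self.streams = _NoiseStreams(config.seed, n)
        self.t_inj, self.y0 = _injection_arrays(config)
        self.x = np.zeros(n)
        self.y = self.y0.copy()
        self.vx = np.zeros(n)
        self.vy = np.zeros(n)
        self.status = np.full(n, _STATUS["flowing"], dtype=np.int8)
        self.active = np.zeros(n, dtype=bool)
        self.entered = np.zeros(n, dtype=bool)
        self.event_time = np.full(n, np.nan)
        self.re_p_max = 0.0
        self.re_p_violations = 0
        self.records: list[tuple] = []

    def _activate(self, t, dt):
        newly = (~self.active
                 & (self.status == _STATUS["flowing"])
                 & (self.t_inj <= t + 1e-12))
        if np.any(newly):
            idx = np.nonzero(newly)[0]
            w = self.env.waveform
            self.vx[idx] = w(self.t_inj[idx])
            self.vy[idx] = 0.0
            self.active[idx] = True

    def _step(self, t, dt):
        env = self.env
        idx = np.nonzero(self.active)[0]
        if idx.size == 0:
            return
        x = self.x[idx]
        y = self.y[idx]
        ubx, uby = env.blood_velocity(x, y, t)
        eta = env.local_viscosity(x, y, t)
        mdx, mdy = env.magnetic_drift(x, y, eta)

        if self.cfg.brownian:
            z = self.streams.normals(idx)
            dcoef = env.diffusivity(eta)
            bx = np.sqrt(2.0 * dcoef * dt) * z[:, 0]
            by = np.sqrt(2.0 * dcoef * dt) * z[:, 1]
        else:
            bx = by = 0.0

        if self.cfg.integrator == "overdamped":
            upx = ubx + mdx + bx / dt
            upy = uby + mdy + by / dt
            xn = x + upx * dt
            yn = y + upy * dt
            self.vx[idx] = upx
            self.vy[idx] = upy
        else:
            tau = env.tau_p(eta)
            damp = 3.0 * math.pi * eta * env.diameter
            fbx = bx / dt * damp    # Brownian displacement as equivalent force
            fby = by / dt * damp
            usx = ubx + mdx + fbx / damp
            usy = uby + mdy + fby / damp
            e = np.exp(-dt / tau)
            vx0 = self.vx[idx]
            vy0 = self.vy[idx]
            xn = x + usx * dt + (vx0 - usx) * tau * (1.0 - e)
            yn = y + usy * dt + (vy0 - usy) * tau * (1.0 - e)
            self.vx[idx] = usx + (vx0 - usx) * e
            self.vy[idx] = usy + (vy0 - usy) * e
            upx, upy = self.vx[idx], self.vy[idx]

        if not np.all(np.isfinite(xn)) or not np.all(np.isfinite(yn)):
            bad = idx[~(np.isfinite(xn) & np.isfinite(yn))]
            raise FloatingPointError(
                f"non-finite force/position for particles {bad[:5]} "
                f"at t={t:.6f}")

        # particle Reynolds guard (Stokes-regime assumption)
        slip = np.hypot(upx - ubx, upy - uby)
        re_p = env.rho_eff * slip * env.diameter / eta
        m = float(np.max(re_p)) if re_p.size else 0.0
        self.re_p_max = max(self.re_p_max, m)
        self.re_p_violations += int(np.sum(re_p >= 1.0))

        # wall interaction
        r_h = env.r_h
        w = env.geom.width
        low = yn < r_h
        high = yn > w - r_h
        hit = low | high
        if np.any(hit):
            hidx = np.nonzero(hit)[0]
            at_bottom = low[hidx]
            y_c = np.where(at_bottom, r_h, w - r_h)
            cap = _capture_mask(env, xn[hidx], y_c, at_bottom)
            cap_global = idx[hidx[cap]]
            self.status[cap_global] = _STATUS["captured"]
            self.active[cap_global] = False
            self.event_time[cap_global] = t + dt
            yn[hidx[cap]] = y_c[cap]
            self.vx[cap_global] = 0.0
            self.vy[cap_global] = 0.0
            refl = hidx[~cap]
            yn[refl] = np.clip(2.0 * np.where(low[refl], r_h, w - r_h)
                               - yn[refl], r_h, w - r_h)
            self.vy[idx[refl]] *= -1.0

        self.x[idx] = xn
        self.y[idx] = yn

        flowing = self.status[idx] == _STATUS["flowing"]
        f0, f1 = env.geom.magnet_footprint
        self.entered[idx[(xn >= f0)]] = True

        # downstream exit is terminal; upstream excursions (x < 0) stay live
        # in a virtual plug-flow extension of the vessel and re-enter with
        # the next forward phase.  A particle carried further upstream than
        # one channel length is written off as washed out.
        out = flowing & (xn > env.geom.length)
        back = flowing & (xn < -env.geom.length)
        self.status[idx[out]] = _STATUS["exited"]
        self.status[idx[back]] = _STATUS["washed_out"]
        gone = out | back
        self.active[idx[gone]] = False
        self.event_time[idx[gone]] = t + dt

    def run(self, record_stride: int = 0) -> CaptureResult:
        cfg = self.cfg
        t = 0.0
        n_steps = int(round(cfg.t_max / cfg.dt))
        last_inj = max(cfg.injection_times)
        for k in range(n_steps):
            self._activate(t, cfg.dt)
            self._step(t, cfg.dt)
            t += cfg.dt
            if record_stride and k % record_stride == 0:
                for i in np.nonzero(self.active)[0]:
                    self.records.append(
                        (t, int(i), self.x[i], self.y[i],
                         self.vx[i], self.vy[i], "flowing"))
            if t > last_inj and not np.any(self.active):
                break
        return self._result()

    def _result(self) -> CaptureResult:
        captured = self.status == _STATUS["captured"]
        flowing = self.status == _STATUS["flowing"]
        exited = self.status == _STATUS["exited"]
        washed = self.status == _STATUS["washed_out"]
        f1 = self.env.geom.magnet_footprint[1]
        self.entered |= captured
        ent = self.entered
        n_captured = int(np.sum(captured & ent))
        eps_out = int(np.sum(ent & (exited | (flowing & (self.x > f1)))))
        unresolved = int(np.sum(ent)) - n_captured - eps_out
        return CaptureResult(
            eps_in=int(np.sum(ent)), eps_out=eps_out, n_captured=n_captured,
            n_flowing_at_tmax=unresolved, seed=self.cfg.seed,
            n_injected=self.cfg.n_particles, re_p_max=self.re_p_max,
            re_p_violations=self.re_p_violations)

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["t", "particle", "x", "y", "vx", "vy", "status"])


def step(state: ParticleState, t: float, dt: float, env: TransportEnv,
         rng: np.random.Generator | None = None) -> ParticleState:
    """Advance a single flowing particle one time step.

    Convenience single-particle interface over the vectorized stepper;
    Brownian noise is drawn from ``rng`` (omit for a noiseless step).
    """
    if state.status != "flowing":
        raise ValueError("can only step a flowing particle")
    cfg = env.config
    x = np.array([state.position[0]])
    y = np.array([state.position[1]])
    ubx, uby = env.blood_velocity(x, y, t)
    eta = env.local_viscosity(x, y, t)
    mdx, mdy = env.magnetic_drift(x, y, eta)
    if cfg.brownian and rng is not None:
        dcoef = env.diffusivity(eta)
        z = rng.standard_normal(2)
        bx, by = np.sqrt(2.0 * dcoef * dt) * z
    else:
        bx = by = 0.0
    if cfg.integrator == "overdamped":
        upx = ubx[0] + float(mdx[0]) + bx / dt
        upy = uby[0] + float(mdy[0]) + by / dt
        pos = state.position + np.array([upx, upy]) * dt
        vel = np.array([upx, upy])
    else:
        eta_s = float(np.asarray(eta).ravel()[0])
        tau = env.tau_p(eta_s)
        damp = 3.0 * math.pi * eta_s * env.diameter
        usx = ubx[0] + float(mdx[0]) + bx / dt
        usy = uby[0] + float(mdy[0]) + by / dt
        e = math.exp(-dt / tau)
        us = np.array([usx, usy])
        pos = (state.position + us * dt
               + (state.velocity - us) * tau * (1.0 - e))
        vel = us + (state.velocity - us) * e
    if not np.all(np.isfinite(pos)):
        raise FloatingPointError(f"non-finite state at t={t:.6f}")
    return replace(state, position=pos, velocity=vel)


def run(config: SimulationConfig,
        record_stride: int = 0) -> CaptureResult | tuple[CaptureResult,
                                                         pd.DataFrame]:
    """Integrate all particles to exit, capture, or t_max.

    Returns the :class:`CaptureResult`; with ``record_stride > 0`` also a
    trajectory DataFrame sampled every that many steps.
    """
    eng = _Engine(config)
    res = eng.run(record_stride=record_stride)
    if record_stride:
        return res, eng.trajectory_frame()
    return res


def _child_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0]
               % (2 ** 31))


def sweep_core_size(config: SimulationConfig,
                    radii: list[float]) -> pd.DataFrame:
    """Capture efficiency versus core radius (same seed base, per-radius
    child seeds).  Radii in metres."""
    rows = []
    for i, r in enumerate(radii):
        if not 10e-9 <= r <= 2e-6:
            raise ValueError("core radius must lie in [10 nm, 2 um]")
        cfg = replace(config,
                      particle=replace(config.particle, core_radius=r),
                      seed=_child_seed(config.seed, i))
        res = run(cfg)
        rows.append({"radius_m": r, "eps_in": res.eps_in,
                     "eps_out": res.eps_out, "captured": res.n_captured,
                     "unresolved": res.n_flowing_at_tmax,
                     "efficiency_pct": res.efficiency_pct,
                     "stderr_pct": res.stderr_pct})
    return pd.DataFrame(rows)


def sweep_coating(config: SimulationConfig,
                  coatings: list[tuple[str | None, float]]) -> pd.DataFrame:
    """Capture efficiency over (coating material, thickness) pairs.

    A bare-core baseline row is always included first.  All rows share the
    run seed (common random numbers) so coating effects are compared on
    paired trajectories; a zero-thickness coating is bit-identical to the
    bare core.
    """
    all_rows = [(None, 0.0)] + [c for c in coatings if c[1] > 0 or c[0]]
    rows = []
    for mat_name, thick in all_rows:
        if not 0.0 <= thick <= 50e-9:
            raise ValueError("shell thickness must lie in [0, 50 nm]")
        shell = MATERIALS[mat_name] if mat_name else None
        cfg = replace(config, particle=replace(
            config.particle, shell=shell,
            shell_thickness=thick if shell else 0.0))
        res = run(cfg)
        rows.append({"material": mat_name or "bare",
                     "thickness_m": thick if shell else 0.0,
                     "eps_in": res.eps_in, "eps_out": res.eps_out,
                     "captured": res.n_captured,
                     "unresolved": res.n_flowing_at_tmax,
                     "efficiency_pct": res.efficiency_pct,
                     "stderr_pct": res.stderr_pct})
    return pd.DataFrame(rows)
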