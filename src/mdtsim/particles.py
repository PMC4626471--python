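"""Materials and the forces on a core/shell magnetic drug carrier.

A carrier is a spherical magnetic core (Fe3O4, Fe2O3, or Fe) optionally
wrapped in a non-magnetic biocompatible shell (Au, SiO2, PEG).  The
magnetophoretic force acts on the core alone (the shell has zero
susceptibility); Stokes drag and the Brownian amplitude see the whole
hydrodynamic sphere.

Forces
------
magnetophoretic   F_M = 2 pi mu_b r_core^3 K grad|H|^2,
                  K = (mu_p - mu_b)/(mu_p + 2 mu_b)   (Clausius-Mossotti)
Stokes drag       F_D = (m_p / tau_p)(u_b - u_p) = 3 pi eta D (u_b - u_p),
                  tau_p = rho_eff D^2 / (18 eta)
Brownian          F_B = zeta sqrt(12 pi r_h eta k_B T / dt) per component,
                  zeta ~ N(0, 1) independent per component and step

The Brownian amplitude together with the Stokes mobility 1/(6 pi eta r_h)
reduces exactly to Einstein free diffusion, MSD = 2 (k_B T / 6 pi eta r_h) t
per dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import KB, MU0

__all__ = [
    "Material",
    "MATERIALS",
    "register_material",
    "ParticleSpec",
    "ForceVector",
    "clausius_mossotti",
    "magnetophoretic_force",
    "relaxation_time",
    "drag_force",
    "brownian_force",
]


@dataclass(frozen=True)
class Material:
    """A bulk material: volume susceptibility and density."""

    name: str
    density: float                    # kg/m^3
    susceptibility: float = 0.0       # dimensionless volume susceptibility
    viscosity: float | None = None    # kg/(m s), fluids only

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.susceptibility <= -1.0:
            raise ValueError("susceptibility must exceed -1")


#: shipped database: magnetic cores, blood, and coating materials
MATERIALS: dict[str, Material] = {
    "Fe3O4": Material("Fe3O4", density=5230.0, susceptibility=3.1),
    "Fe2O3": Material("Fe2O3", density=4890.0, susceptibility=2.5),
    "Fe": Material("Fe", density=7760.0, susceptibility=3.9),
    "blood": Material("blood", density=1060.0, susceptibility=-6.6e-7,
                      viscosity=0.0035),
    "Au": Material("Au", density=19320.0),
    "SiO2": Material("SiO2", density=2648.0),
    "PEG": Material("PEG", density=1114.0),
}


def register_material(material: Material, overwrite: bool = False) -> None:
    """Add a material to the shared database by name."""
    if material.name in MATERIALS and not overwrite:
        raise ValueError(f"material {material.name!r} already registered")
    MATERIALS[material.name] = material


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical core/shell drug carrier.

    Derived quantities use spherical (3D) volumes: the carrier mass is the
    volume-weighted sum of core and shell, and the effective density is
    mass over total volume.  With zero shell thickness the effective
    density equals the core density exactly.
    """

    core: Material
    core_radius: float                 # m
    shell: Material | None = None
    shell_thickness: float = 0.0       # m

    def __post_init__(self):
        if self.core_radius <= 0:
            raise ValueError("core radius must be positive")
        if self.shell_thickness < 0:
            raise ValueError("shell thickness must be non-negative")
        if self.shell_thickness > 0 and self.shell is None:
            raise ValueError("shell material required for non-zero thickness")

    @property
    def total_radius(self) -> float:
        return self.core_radius + self.shell_thickness

    @property
    def hydrodynamic_radius(self) -> float:
        return self.total_radius

    @property
    def diameter(self) -> float:
        return 2.0 * self.total_radius

    @property
    def core_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.core_radius ** 3

    @property
    def total_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.total_radius ** 3

    @property
    def shell_volume(self) -> float:
        return self.total_volume - self.core_volume

    @property
    def mass(self) -> float:
        m = self.core.density * self.core_volume
        if self.shell is not None:
            m += self.shell.density * self.shell_volume
        return m

    @property
    def effective_density(self) -> float:
        if self.shell_thickness == 0.0:
            return self.core.density
        return self.mass / self.total_volume


@dataclass(frozen=True)
class ForceVector:
    """A 2D force with a provenance tag."""

    vector: np.ndarray     # N
    kind: Literal["magnetophoretic", "drag", "brownian"]

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (2,) or not np.all(np.isfinite(v)):
            raise ValueError("force must be a finite 2-vector")
        object.__setattr__(self, "vector", v)

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.vector))


def clausius_mossotti(chi_p: float, chi_b: float) -> float:
    """Clausius-Mossotti contrast factor K in [-0.5, 1.0]."""
    if chi_p <= -1.0 or chi_b <= -1.0:
        raise ValueError("susceptibilities must exceed -1")
    mu_p = MU0 * (1.0 + chi_p)
    mu_b = MU0 * (1.0 + chi_b)
    return (mu_p - mu_b) / (mu_p + 2.0 * mu_b)


def magnetophoretic_force(spec: ParticleSpec, grad_h2,
                          chi_b: float = -6.6e-7) -> ForceVector:
    """Magnetophoretic force on the carrier's magnetic core, N.

    Only the core volume responds to the field; the shell is magnetically
    inert, so a coated particle feels exactly the force of its bare core.
    """
    g = np.asarray(grad_h2, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("grad|H|^2 must be finite")
    K = clausius_mossotti(spec.core.susceptibility, chi_b)
    mu_b = MU0 * (1.0 + chi_b)
    f = 2.0 * math.pi * mu_b * spec.core_radius ** 3 * K * g
    return ForceVector(vector=f, kind="magnetophoretic")


def relaxation_time(spec: ParticleSpec, eta: float) -> float:
    """Momentum relaxation time tau_p = rho_eff D^2 / (18 eta), s."""
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return spec.effective_density * spec.diameter ** 2 / (18.0 * eta)


def drag_force(spec: ParticleSpec, u_b, u_p, eta: float) -> ForceVector:
    """Stokes drag F_D = (m_p / tau_p)(u_b - u_p), N.

    Algebraically identical to 3 pi eta D (u_b - u_p) because m_p and
    tau_p share the effective density.
    """
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    slip = np.asarray(u_b, dtype=float) - np.asarray(u_p, dtype=float)
    f = spec.mass / relaxation_time(spec, eta) * slip
    return ForceVector(vector=f, kind="drag")


def brownian_amplitude(spec: ParticleSpec, eta: float, temperature: float,
                       dt: float) -> float:
    """Per-component Gaussian force amplitude sqrt(12 pi r_h eta k_B T / dt), N."""
    if temperature <= 0 or dt <= 0:
        raise ValueError("temperature and time step must be positive")
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return math.sqrt(
        12.0 * math.pi * spec.hydrodynamic_radius * eta * KB * temperature / dt)


def brownian_force(spec: ParticleSpec, eta: float, temperature: float,
                   dt: float, rng: np.random.Generator) -> ForceVector:
    """One stochastic Brownian force sample, N.

    Each component is an independent standard-normal draw scaled by the
    fluctuation-dissipation amplitude; the amplitude depends only on the
    hydrodynamic radius, viscosity, temperature and time step.
    """
    amp = brownian_amplitude(spec, eta, temperature, dt)
    return ForceVector(vector=amp * rng.standard_normal(2), kind="brownian")


def diffusion_coefficient(spec: ParticleSpec, eta: float,
                          temperature: float) -> float:
    """Stokes-Einstein diffusivity k_B T / (6 pi eta r_h), m^2/s."""
    return KB * temperature / (6.0 * math.pi * eta * spec.hydrodynamic_radius)
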