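# mdtsim

A desk-scale simulator of **magnetic drug targeting (MDT)**: how efficiently
an implanted permanent magnet captures drug-loaded magnetic nanoparticles
out of pulsatile arterial blood flow, as a function of particle size, core
material (Fe3O4, Fe2O3, Fe), and biocompatible coating (Au, SiO2, PEG).

It is written for people designing magnetic drug carriers or capture
experiments who want a fast, transparent 2D model instead of a full FEM
pipeline: every component — field, rheology, forces — is closed-form or a
simple solver, and every run is reproducible from a seed.

## Model

A straight 2D vessel (width 4 mm) carries blood with Generalised Power Law
viscosity, eta = lambda(gd) |gd|^(n(gd)-1), driven by a degree-9 polynomial
pulsatile waveform (cardiac period 1 s, mean 0.10 m/s, inlet Re ~ 121).
Beside it sits a uniformly magnetized rectangular magnet whose exterior
field is analytic (equivalent charge-sheet solution), calibrated so that
|B| = 0.5 T and |grad B| = 1.80 T/cm at the vessel centre.

Each spherical carrier (magnetic core, optional non-magnetic shell) obeys

    m_p d²r/dt² = F_M + F_D + F_B

with the magnetophoretic force F_M = 2 pi mu_b r_core³ K grad|H|²
(K the Clausius–Mossotti factor, ~0.51 for Fe3O4 in blood), Stokes drag
F_D = 3 pi eta D (u_b − u_p), and Gaussian Brownian forcing
F_B = zeta sqrt(12 pi r_h eta k_B T / dt).  The default integrator is
overdamped (tau_p ~ ns << dt); an inertial exponential integrator is
available and agrees to < 1 nm.

6000 particles (desk runs: 500–1000) enter as plug flow in six bursts over
t = 0–0.05 s.  A particle touching the wall inside the magnet footprint
with a wall-directed magnetic force is captured; all other wall contacts
reflect elastically.  Capture efficiency is

    eps = (eps_in − eps_out) / eps_in × 100 %

over the footprint section of the vessel.  See `docs/methods.md` for
assumptions, calibration details, and known limitations.

## Worked example

```python
from dataclasses import replace
from mdtsim import MATERIALS, ParticleSpec, run
from mdtsim.config import default_config

cfg = default_config(seed=1)                     # calibrates the magnet
cfg = replace(cfg, n_particles=1000,
              particle=ParticleSpec(core=MATERIALS["Fe3O4"],
                                    core_radius=50e-9))
res = run(cfg)
print(res)
print(f"capture efficiency = {res.efficiency_pct:.2f} %")
```

prints

```
CaptureResult(eps_in=1000, eps_out=979, n_captured=17, n_flowing_at_tmax=4,
              seed=1, n_injected=1000, re_p_max=0.000149..., re_p_violations=0)
capture efficiency = 1.71 %
```

All 1000 injected 50 nm carriers entered the magnet section; 979 escaped
downstream, 17 were pinned to the wall by the field, and 4 were still in
transit at the 5 s cutoff (excluded from the denominator).  The efficiency,
17/996 = 1.71 %, shows why superparamagnetic-size carriers are hard to hold
in arterial flow — the magnetophoretic force scales with r³.  Rerunning
with `core_radius=2e-6` (a 2 um core) gives ~60 %: the near half of the
channel is captured completely, while particles crossing from the far wall
outrun the localized field.

The same sweeps are available from the shell:

```sh
mdtsim simulate --seed 1 --n-particles 1000 --out run1
mdtsim sweep-size --radii 50,500,2000 --n-particles 400 --seed 1
mdtsim sweep-coating --materials Au,SiO2,PEG --thicknesses 5,25,50
mdtsim reproduce-figures --out figures --scale desk
```

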