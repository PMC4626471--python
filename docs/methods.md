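# Methods

`mdtsim` estimates the capture efficiency of magnetic drug targeting (MDT)
in a 2D reduction of arterial flow: an implanted rectangular permanent
magnet beside a straight 4 mm vessel, pulsatile shear-thinning blood flow,
and Lagrangian Monte Carlo transport of spherical core/shell nanocarriers.

## Magnetic field

The magnet is a uniformly magnetized rectangle (infinite out of plane).  Its
exterior field is the closed-form equivalent magnetic-charge-sheet solution:
magnetization M = B_rem/mu0 replaced by sheets of surface charge +/-M on the
faces normal to the magnetization axis.  The solution satisfies div B = 0
and curl H = 0 exactly outside the magnet, decays as a 2D dipole (r^-2) in
the far field, and has a closed-form Jacobian, so the magnetophoretic drive
term grad|H|^2 = 2 J^T H is analytic (no finite differences in the force
path).  Blood's diamagnetic susceptibility (chi_b = -6.6e-7) perturbs the
field at the 1e-6 level and is retained only in the constitutive relation
B = mu0(1 + chi_b)H; its feedback on the source is neglected.  The interior
field (and hence mu_r of the magnet material) is never needed and never
evaluated.

### Field calibration

The literature pins the field only at the target: |B| ~ 0.5 T and
|grad|B|| = 1.80 T/cm at the vessel centre, with the source strength capped
at 2 T.  The magnet geometry itself is not published, so the simulator
reconstructs it by calibration: the stand-off distance along the
magnetization axis fixes the gradient-to-field ratio (360 /m), and the
remanence then scales |B| linearly.  Two consequences are worth stating
plainly:

* A ratio of 360 /m at a point >= 2 mm outside the magnet (the centre of a
  4 mm vessel with the magnet beyond the wall) forces a magnet only a few
  mm wide.  The default cross-section is 3.6 mm x 20 mm, for which the
  calibrated magnet face lands 0.23 mm outside the vessel wall — an
  implant pressed against the adventitia.  Wide magnets (>= 1 cm) cannot
  reach the ratio at any stand-off or remanence and fail calibration with a
  best-achievable report.
* The equivalent-source remanence required is 2.63 T.  The 2 T cap is
  interpreted as a cap on the *produced field strength* (it is checked at
  the magnet face, where the exterior field is strongest, ~1.2 T here); an
  equivalent-source B_rem above 2 T is a property of the elongated
  cross-section, not a stronger field.  A validation guard rejects
  B_rem > 4 T.

## Blood rheology and flow

Viscosity follows the Generalised Power Law (Ballyk constants:
eta_inf = 0.0035, d_eta = 0.025 kg/(m s), a = 50, b = 3, c = 50, d = 4 1/s,
n_inf = 1, d_n = 0.45), Newtonian at high shear and Power-Law at low shear.
A shear-rate floor gamma_min = 1e-3 1/s guards the gd^(n-1) singularity at
zero shear; the floor matters only at the channel centreline where the
stress vanishes anyway.

The inlet waveform is a degree-9 polynomial over the 1 s cardiac cycle.
The measured waveform's fitted coefficients are not published; only its
landmarks are: maximum reverse flow at t = 0.12 s, systolic S peak at
t = 0.35 s with about half the diastolic amplitude, diastolic D peak (the
global maximum) at t = 0.85 s.  The generator pins ten coefficients with
ten linear constraints (periodic value and slope; zero slope at the reverse
minimum, S peak, diastolic foot at t = 0.50 s, and D peak; values at the
three named landmarks; the start value v(0) = D/2) and then scales the
polynomial uniformly so the cycle mean is exactly the configured 0.10 m/s.
Scaling preserves extremum locations, periodicity, and the S/D ratio; the
realized D peak is ~2x the mean.  The generator is deterministic.

Velocity profiles are quasi-steady: at each instant the developed planar
profile of the shear-thinning fluid is found by a double bisection (outer:
pressure gradient to match the instantaneous mean; inner: shear rate from
the monotone stress relation tau = eta(gd) gd), with no-slip walls.
Profiles are precomputed on a 33-point grid of mean velocities and
interpolated bilinearly during transport.  By default the flow is plug
outside the magnet footprint (the inlet condition) and developed within it;
both modes are exposed.  Transient Navier-Stokes, the branched outlet tree,
and two-way particle-fluid coupling (dilute suspension, effective
concentration ~1e-6 mg Fe/ml) are out of scope.

## Particle model

Carriers are spheres: a magnetic core (Fe3O4 chi = 3.1, rho = 5230; Fe2O3
2.5, 4890; Fe 3.9, 7760 kg/m^3) with an optional non-magnetic shell (Au
19320, SiO2 2648, PEG 1114 kg/m^3).  The magnetophoretic force
F_M = 2 pi mu_b r_core^3 K grad|H|^2 uses the core radius only (the shell
is magnetically inert); drag and the Brownian amplitude use the full
hydrodynamic radius.  K is the Clausius-Mossotti contrast, ~0.51 for
Fe3O4 in blood.  Design choices where the source notation is ambiguous:

* the radius in the Brownian amplitude sqrt(12 pi r eta k_B T / dt) is the
  hydrodynamic (total) radius — the fluctuation must pair with the drag it
  dissipates against, and the amplitude then reduces exactly to Einstein
  sqrt(2 D dt) displacements;
* the density in tau_p = rho D^2/(18 eta) is the volume-weighted effective
  density of core plus shell;
* temperature defaults to 310 K (body temperature);
* k_B is the SI-exact 1.380649e-23 J/K;
* the viscosity entering the particle forces defaults to the constant
  blood value 0.0035 kg/(m s): a nm-um particle does not see the bulk
  aggregate viscosity of whole blood, and the low-shear Power-Law
  divergence (eta -> 0.64 kg/(m s)) would unphysically freeze particles at
  the centreline.  A "local" mode using the profile's apparent viscosity is
  available in config.

Neglected, following the dilute single-particle picture: interparticle
dipole forces, buoyancy/gravity/lift, magnetic saturation, size-dependent
susceptibility.

## Transport and capture

6000 particles (desk runs use 500-1000) are injected as plug flow in six
equal bursts at t = 0...0.05 s, uniformly over the inlet minus one
hydrodynamic radius per wall.  The default integrator is overdamped
(tau_p ~ 1e-9 s << dt = 1e-4 s): u_p = u_b + F_M/(3 pi eta D) plus the
exact Brownian displacement sqrt(2 D dt) zeta.  An inertial
exponential-integrator mode (exact for the linear drag term, forces frozen
per step) is available and agrees with the overdamped path to < 1 nm for
tau_p/dt < 1e-3; both are unconditionally stable.  The particle Reynolds
number is monitored every step; violations of Re_p < 1 are counted and
reported (they occur only for 2 um particles within ~100 um of the magnet,
where the Stokes drag law is a known approximation).

Wall rule: a particle whose surface reaches a wall is captured — frozen at
the contact point — if the contact lies inside the magnet footprint
(default: the 2 cm of vessel centred on the magnet) AND the wall-normal
component of F_M points into the wall; otherwise it reflects elastically.
This makes the magnet-off null exact (zero captures) while reproducing
wall accumulation next to the source.

Bookkeeping: eps_in counts particles entering the footprint section,
eps_out those leaving it downstream, and eps = (eps_in - eps_out)/eps_in
x 100.  Particles still unresolved at t_max = 5 s are excluded from the
denominator and reported separately.  Particles pushed upstream of the
inlet by the reverse-flow phase remain live in a virtual plug-flow
extension (terminating them there would discard most of an injection burst
as a domain-truncation artifact) and are written off only one channel
length upstream.

Randomness: every particle owns a PCG64 substream spawned from the master
seed (first draw: injection position; then two normals per step), consumed
through per-particle block buffers so the vectorized stepper stays fast.
Runs replay bit-identically, and adding particles does not reshuffle the
noise of existing ones.  The size sweep uses per-radius child seeds; the
coating sweep deliberately shares one seed across rows (common random
numbers) so coating effects are paired comparisons and a zero-thickness
shell is bit-identical to the bare core.

## Problem sizes and what the tests show

Desk-scale runs use N = 500-1000 particles (binomial standard errors of
~0.5-2 percentage points), dt = 1e-4 s, and the 5 s observation window;
the acceptance script runs N = 1000 (50 nm) and N = 500 (2 um).  The
trend suite uses N = 400 per point.

The synthetic waveform emulates the landmark structure of a measured
arterial Doppler waveform, not its full harmonic content; the channel is
straight, so no flow is diverted into branches upstream of the magnet.
Passing tests therefore demonstrate the size and coating dependence of
capture in this reduced geometry, not patient-specific values.  Two known
consequences:

* 50 nm capture lands at ~1.7 % (N = 1000), the same scale as the ~1.85 %
  reported for branched-geometry FEM studies of this configuration.
* 2 um capture saturates at ~60 % here rather than >= 90 %: with the field
  point-calibrated at the vessel centre, the 2D field is necessarily
  localized (~4 mm), and far-wall particles transiting at ~10 cm/s get only
  ~0.2 s of exposure.  Capture of the near half of the channel is complete.
  In a branched artery roughly half the flow (and particle load) leaves
  before the magnet, halving the local velocity and roughly doubling
  exposure.  The monotone size trend (1.7 % -> ~19 % -> ~60 % for
  50 nm -> 500 nm -> 2 um) and the statistical flatness of the coating
  sweep are robust to this reduction.

## Numerical choices

* Field: analytic; the arctangent form atan2(u sign(v), |v|) keeps the
  charge-sheet solution continuous on the sheet plane beyond the strip.
* Profile solve: 257-point transverse grid, 60/64 bisection iterations
  (Newtonian limit reproduces Poiseuille centreline 1.5x mean to < 0.5 %).
* Calibration: bracketed root scan in stand-off (400 log-spaced points,
  Brent refinement), deterministic; infeasible targets raise with the best
  achievable pair.
* Degenerate inputs: zero-pulsatility landmark sets yield a constant
  waveform; zero shell thickness reduces exactly to the bare core; magnet
  off (B_rem = 0) cannot capture by construction.
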