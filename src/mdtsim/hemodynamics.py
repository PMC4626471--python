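"""Blood rheology and pulsatile channel flow.

Viscosity follows the Generalised Power Law of Ballyk and co-workers,

    eta(gd)    = lam(gd) * |gd|^(n(gd) - 1)
    lam(gd)    = eta_inf + d_eta * exp[-(1 + |gd|/a) exp(-b/|gd|)]
    n(gd)      = n_inf - d_n * exp[-(1 + |gd|/c) exp(-d/|gd|)]

which is Newtonian (eta -> eta_inf) at high shear and Power-Law
(lam -> eta_inf + d_eta, n -> n_inf - d_n) at low shear.

The pulsatile inlet waveform is a degree-9 polynomial over one cardiac cycle
reconstructed from its physiological landmarks (maximum reverse flow, systolic
S peak, diastolic D peak), since only the landmarks of the measured Doppler
waveform are known, not the fitted coefficients.  Channel velocity profiles
are quasi-steady: at each instant the developed shear-thinning profile is the
steady planar solution whose cross-sectional mean equals the waveform value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ViscosityParams",
    "FlowWaveform",
    "ChannelGeometry",
    "WaveformFitError",
    "apparent_viscosity",
    "mean_velocity",
    "make_waveform",
    "velocity_profile",
    "DevelopedProfileTable",
    "reynolds",
]


class WaveformFitError(RuntimeError):
    """Raised when the landmark constraint system cannot be satisfied."""


@dataclass(frozen=True)
class ViscosityParams:
    """Generalised Power Law constants (Ballyk fit for human blood).

    Units: eta_inf, d_eta in kg/(m s); a, b, c, d in 1/s; n_inf, d_n
    dimensionless.  ``gamma_min`` is the shear-rate floor that guards the
    Power-Law singularity at zero shear.
    """

    eta_inf: float = 0.0035
    d_eta: float = 0.025
    a: float = 50.0
    b: float = 3.0
    n_inf: float = 1.0
    d_n: float = 0.45
    c: float = 50.0
    d: float = 4.0
    gamma_min: float = 1e-3

    def __post_init__(self):
        if self.eta_inf <= 0 or self.d_eta < 0:
            raise ValueError("eta_inf must be > 0 and d_eta >= 0")
        if min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError("rate constants a, b, c, d must be positive")
        if self.n_inf - self.d_n <= 0:
            raise ValueError("low-shear exponent n_inf - d_n must be positive")
        if self.gamma_min <= 0:
            raise ValueError("gamma_min must be positive")


def apparent_viscosity(gamma_dot, params: ViscosityParams = ViscosityParams()):
    """Apparent viscosity eta(gamma_dot), kg/(m s).  Vectorized.

    The shear-rate magnitude is floored at ``params.gamma_min``.
    """
    g = np.abs(np.asarray(gamma_dot, dtype=float))
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    g = np.maximum(g, params.gamma_min)
    lam = params.eta_inf + params.d_eta * np.exp(
        -(1.0 + g / params.a) * np.exp(-params.b / g))
    n = params.n_inf - params.d_n * np.exp(
        -(1.0 + g / params.c) * np.exp(-params.d / g))
    out = lam * g ** (n - 1.0)
    if np.isscalar(gamma_dot) or np.ndim(gamma_dot) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class WaveformLandmarks:
    """Cardiac-cycle landmarks of the arterial velocity waveform.

    Times in seconds within one period; amplitudes as multiples of the cycle
    mean.  The systolic (S) peak defaults to half the diastolic (D) peak,
    matching the measured waveform shape.
    """

    t_reverse_min: float = 0.12
    t_s_peak: float = 0.35
    t_foot: float = 0.50          # diastolic foot before the rapid acceleration
    t_d_peak: float = 0.85
    rev_amplitude: float = -0.5   # x mean, before mean-normalisation
    d_amplitude: float = 3.5      # x mean, before mean-normalisation
    s_over_d: float = 0.5
    start_over_d: float = 0.5     # v(0) as a fraction of the D peak


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic mean-velocity waveform as a degree <= 9 polynomial."""

    coefficients: tuple[float, ...]   # ascending powers of t, m/s
    period: float = 1.0
    landmarks: WaveformLandmarks | None = None

    def __call__(self, t):
        tm = np.mod(t, self.period)
        return np.polynomial.polynomial.polyval(tm, self.coefficients)

    @property
    def mean(self) -> float:
        c = np.asarray(self.coefficients)
        k = np.arange(len(c))
        return float(np.sum(c * self.period ** k / (k + 1)))


def mean_velocity(t, w: FlowWaveform):
    """Instantaneous cross-sectional mean velocity, m/s (periodic in t)."""
    out = w(t)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def make_waveform(mean: float = 0.10, period: float = 1.0,
                  landmarks: WaveformLandmarks = WaveformLandmarks(),
                  seed: int | None = None) -> FlowWaveform:
    """Construct the degree-9 landmark-constrained pulsatile waveform.

    The ten polynomial coefficients are pinned by ten linear constraints:
    periodic continuity of value and slope, zero slope at the four landmark
    extrema (reverse minimum, S peak, diastolic foot, D peak), prescribed
    values at the reverse minimum, S peak, D peak, and cycle start.  The
    result is then scaled uniformly so the cycle mean is exact; scaling
    preserves extremum locations, periodicity, and the S/D amplitude ratio.
    Deterministic; ``seed`` is accepted for interface symmetry but unused.
    """
    lm = landmarks
    for t in (lm.t_reverse_min, lm.t_s_peak, lm.t_foot, lm.t_d_peak):
        if not 0.0 < t < period:
            raise ValueError("landmark times must lie inside (0, period)")

    deg = 9
    k = np.arange(deg + 1)

    def val_row(t):
        return t ** k

    def der_row(t):
        r = np.zeros(deg + 1)
        r[1:] = k[1:] * t ** (k[1:] - 1)
        return r

    a_d = lm.d_amplitude * mean
    a_s = lm.s_over_d * a_d
    a_r = lm.rev_amplitude * mean
    a_0 = lm.start_over_d * a_d

    rows, rhs = [], []
    rows.append(val_row(0.0) - val_row(period)); rhs.append(0.0)
    rows.append(der_row(0.0) - der_row(period)); rhs.append(0.0)
    for t_ext in (lm.t_reverse_min, lm.t_s_peak, lm.t_foot, lm.t_d_peak):
        rows.append(der_row(t_ext)); rhs.append(0.0)
    rows.append(val_row(lm.t_reverse_min)); rhs.append(a_r)
    rows.append(val_row(lm.t_s_peak)); rhs.append(a_s)
    rows.append(val_row(lm.t_d_peak)); rhs.append(a_d)
    rows.append(val_row(0.0)); rhs.append(a_0)

    A = np.asarray(rows)
    b = np.asarray(rhs)
    try:
        coef = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        res = np.linalg.lstsq(A, b, rcond=None)
        raise WaveformFitError(
            f"landmark constraint system is singular (residual {res[1]})"
        ) from exc
    resid = float(np.max(np.abs(A @ coef - b)))
    if resid > 1e-9 * max(1.0, abs(mean), abs(a_d)):
        raise WaveformFitError(f"constraint residual {resid:g} m/s too large")
    raw_mean = float(np.sum(coef * period ** k / (k + 1))) / period
    if mean != 0.0:
        if abs(raw_mean) < 1e-12 * abs(mean):
            raise WaveformFitError(
                "landmark waveform has (near-)zero mean; cannot normalise")
        coef = coef * (mean / raw_mean)
    return FlowWaveform(coefficients=tuple(coef), period=period, landmarks=lm)


@dataclass(frozen=True)
class ChannelGeometry:
    """Straight 2D vessel: y in [0, width] across, x increasing downstream."""

    width: float = 0.004
    length: float = 0.04
    magnet_footprint: tuple[float, float] = (0.01, 0.03)
    blood_density: float = 1060.0

    def __post_init__(self):
        if self.width <= 0 or self.length <= 0:
            raise ValueError("width and length must be positive")
        f0, f1 = self.magnet_footprint
        if not (0.0 <= f0 < f1 <= self.length):
            raise ValueError("magnet footprint must lie within [0, length]")
        if self.blood_density <= 0:
            raise ValueError("blood density must be positive")


def reynolds(rho: float, v: float, l: float, eta: float) -> float:
    """Reynolds number rho * v * l / eta."""
    for name, val in (("rho", rho), ("v", v), ("l", l), ("eta", eta)):
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val}")
    return rho * v * l / eta


def _solve_developed(v_mean: float, width: float, params: ViscosityParams,
                     ny: int = 257) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady planar profile of the shear-thinning fluid at one mean velocity.

    Returns (y grid, u(y), shear_rate(y) >= 0).  The pressure-gradient
    magnitude G is found by bisection so the cross-sectional mean matches;
    at each y the shear rate inverts the monotone stress relation
    tau = eta(gd) gd by bisection.
    """
    y = np.linspace(0.0, width, ny)
    if v_mean == 0.0:
        return y, np.zeros(ny), np.zeros(ny)
    sgn = 1.0 if v_mean > 0 else -1.0
    vm = abs(v_mean)
    half = width / 2.0

    def profile(G):
        tau = G * np.abs(half - y)          # |shear stress|
        lo = np.zeros(ny)
        hi = tau / params.eta_inf + params.gamma_min
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            stress = apparent_viscosity(mid, params) * mid
            too_low = stress < tau
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        gd = 0.5 * (lo + hi)
        dudy = np.where(y < half, gd, -gd)
        u = np.concatenate(([0.0], np.cumsum(
            0.5 * (dudy[1:] + dudy[:-1]) * np.diff(y))))
        return u, gd

    def mean_of(G):
        u, _ = profile(G)
        return np.trapezoid(u, y) / width

    g_hi = 12.0 * params.eta_inf * vm / width ** 2
    while mean_of(g_hi) < vm:
        g_hi *= 2.0
        if g_hi > 1e12:
            raise RuntimeError("pressure-gradient bracket failed")
    g_lo = 0.0
    for _ in range(60):
        g_mid = 0.5 * (g_lo + g_hi)
        if mean_of(g_mid) < vm:
            g_lo = g_mid
        else:
            g_hi = g_mid
    u, gd = profile(0.5 * (g_lo + g_hi))
    return y, sgn * u, gd


class DevelopedProfileTable:
    """Precomputed developed profiles over a grid of mean velocities.

    Quasi-steady lookup for the particle stepper: ``u(y, v_mean)`` and
    ``shear(y, v_mean)`` interpolate bilinearly in the (|v_mean|, y) table
    and use the antisymmetry u(y, -v) = -u(y, v).
    """

    def __init__(self, width: float, v_max: float,
                 params: ViscosityParams = ViscosityParams(),
                 n_v: int = 33, ny: int = 257):
        self.width = width
        self.params = params
        self.v_grid = np.linspace(0.0, max(v_max, 1e-6), n_v)
        u_rows, g_rows = [], []
        for v in self.v_grid:
            y, u, gd = _solve_developed(v, width, params, ny)
            u_rows.append(u)
            g_rows.append(gd)
        self.y_grid = y
        self.u_tab = np.asarray(u_rows)     # (n_v, ny)
        self.g_tab = np.asarray(g_rows)

    def _interp(self, tab, y, v_mean):
        y = np.clip(y, 0.0, self.width)
        va = np.abs(v_mean)
        iv = np.clip(np.searchsorted(self.v_grid, va) - 1, 0,
                     len(self.v_grid) - 2)
        iy = np.clip(np.searchsorted(self.y_grid, y) - 1, 0,
                     len(self.y_grid) - 2)
        fv = (va - self.v_grid[iv]) / (self.v_grid[iv + 1] - self.v_grid[iv])
        fy = (y - self.y_grid[iy]) / (self.y_grid[iy + 1] - self.y_grid[iy])
        t00 = tab[iv, iy]
        t01 = tab[iv, iy + 1]
        t10 = tab[iv + 1, iy]
        t11 = tab[iv + 1, iy + 1]
        return ((1 - fv) * ((1 - fy) * t00 + fy * t01)
                + fv * ((1 - fy) * t10 + fy * t11))

    def u(self, y, v_mean):
        """Axial velocity at transverse position(s) y for a given mean."""
        return np.sign(v_mean) * self._interp(self.u_tab, y, v_mean)

    def shear(self, y, v_mean):
        """Local shear-rate magnitude at y for a given mean."""
        return self._interp(self.g_tab, y, v_mean)


def velocity_profile(y, t: float, geom: ChannelGeometry,
                     params: ViscosityParams, w: FlowWaveform,
                     mode: str = "developed"):
    """Axial blood velocity at transverse position y and time t, m/s.

    mode='plug' returns the uniform instantaneous mean; mode='developed'
    returns the quasi-steady shear-thinning profile with no-slip walls.
    """
    ya = np.asarray(y, dtype=float)
    if np.any(ya < 0) or np.any(ya > geom.width):
        raise ValueError(f"y must lie in [0, {geom.width}] m")
    vm = mean_velocity(t, w)
    if mode == "plug":
        out = np.full_like(ya, vm, dtype=float)
    elif mode == "developed":
        yg, u, _ = _solve_developed(vm, geom.width, params)
        out = np.interp(ya, yg, u)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out)
    return out
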