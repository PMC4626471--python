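"""Analytic 2D magnetostatics of a uniformly magnetized rectangular magnet.

The exterior field of a uniformly magnetized rectangle (infinite in the
out-of-plane direction) is computed from the equivalent magnetic-charge-sheet
solution: the magnetization M = B_rem / mu0 along the magnetization axis is
replaced by two sheets of magnetic surface charge +/-M on the faces normal to
the axis.  The resulting H field is curl- and divergence-free everywhere
outside the magnet, continuous, and decays as a 2D dipole (|r|^-2) in the far
field.  Both H and its spatial Jacobian are closed-form (logarithms and
arctangents), so the magnetophoretic drive term grad|H|^2 is analytic as well.

Blood is only very weakly diamagnetic (chi_b ~ -6.6e-7), so its feedback on
the source field is neglected; the constitutive relation B = mu0 (1 + chi_b) H
is honoured when sampling the field inside the vessel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import MU0

__all__ = [
    "MagnetSpec",
    "BloodMagnetics",
    "FieldSample",
    "MagnetDomainError",
    "CalibrationError",
    "field_at",
    "grad_h2_at",
    "calibrate_to_target",
    "export_field_grid",
]

#: validation guard on the remanent flux density of a single source (T).  The
#: physically meaningful cap is on the *produced* field strength (<= 2 T, the
#: strength of the implanted source this model emulates), which is enforced by
#: :func:`calibrate_to_target`; B_rem itself is an equivalent-source parameter
#: and may exceed 2 T for elongated magnets.
B_REM_MAX = 4.0

#: cap on the exterior field strength produced by a calibrated source (T)
B_FIELD_MAX = 2.0


class MagnetDomainError(ValueError):
    """Raised when a field sample is requested inside the magnet body."""


class CalibrationError(RuntimeError):
    """Raised when no magnet placement can reach the requested field targets."""

    def __init__(self, message: str, best_b: float | None = None,
                 best_grad: float | None = None):
        super().__init__(message)
        self.best_b = best_b
        self.best_grad = best_grad


@dataclass(frozen=True)
class MagnetSpec:
    """A rectangular permanent magnet, uniformly magnetized in-plane.

    Parameters
    ----------
    b_rem : float
        Remanent flux density magnitude along the magnetization axis, T.
    center : tuple of float
        Position of the rectangle centre, m.
    width : float
        Extent perpendicular to the magnetization axis, m.
    height : float
        Extent along the magnetization axis, m.
    axis : tuple of float
        Magnetization direction (unit vector).
    mu_r : float
        Relative permeability of the magnet material.  Only the interior
        field depends on it, which this simulator never evaluates; stored
        for fidelity.
    """

    b_rem: float
    center: tuple[float, float]
    width: float
    height: float
    axis: tuple[float, float] = (0.0, 1.0)
    mu_r: float = 1.05

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("magnet width and height must be positive")
        if not (0.0 <= self.b_rem <= B_REM_MAX):
            raise ValueError(
                f"b_rem must lie in [0, {B_REM_MAX}] T, got {self.b_rem}")
        nrm = math.hypot(*self.axis)
        if not math.isclose(nrm, 1.0, rel_tol=1e-9):
            raise ValueError("magnetization axis must be a unit vector")

    # local frame: e_y || magnetization axis, e_x = axis rotated by -90 deg
    @property
    def _frame(self) -> np.ndarray:
        ax, ay = self.axis
        return np.array([[ay, -ax], [ax, ay]])  # rows: e_x_local, e_y_local

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float) - np.asarray(self.center)
        lx, ly = self._frame @ p
        return bool(abs(lx) < self.width / 2 and abs(ly) < self.height / 2)


@dataclass(frozen=True)
class BloodMagnetics:
    """Linearized magnetic response of blood, M_b = chi_b H with chi_b = alpha*beta.

    The arctangent magnetization curve parameters alpha (A/m) and beta (m/A)
    may be supplied; in the linear (Taylor) regime used here only their
    product, the volume susceptibility, enters.
    """

    chi_b: float = -6.6e-7
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.alpha is not None and self.beta is not None:
            prod = self.alpha * self.beta
            if abs(prod - self.chi_b) > 1e-6 * abs(self.chi_b):
                raise ValueError(
                    "alpha*beta must equal chi_b (linearized susceptibility); "
                    f"got alpha*beta={prod:g}, chi_b={self.chi_b:g}")

    @property
    def permeability(self) -> float:
        """mu_b = mu0 (1 + chi_b), N/A^2."""
        return MU0 * (1.0 + self.chi_b)


@dataclass(frozen=True)
class FieldSample:
    """Field quantities at one exterior point."""

    position: tuple[float, float]
    B: np.ndarray          # T
    H: np.ndarray          # A/m
    grad_H2: np.ndarray    # A^2/m^3, gradient of |H|^2


def _sheet_field(x, y, a, b, sigma):
    """H of the +/-sigma charge sheets of a rectangle |x|<=a, |y|<=b (local frame)."""
    hx = np.zeros_like(x)
    hy = np.zeros_like(x)
    for y0, q in ((b, sigma), (-b, -sigma)):
        u1 = x + a
        u2 = x - a
        v = y - y0
        hx = hx + q / (4 * np.pi) * (np.log(u1 * u1 + v * v)
                                     - np.log(u2 * u2 + v * v))
        # atan2(u*sign(v), |v|) == atan(u/v) for v != 0 and gives the correct
        # (zero) limit on the sheet plane beyond the strip
        sv = np.sign(v)
        hy = hy + q / (2 * np.pi) * (np.arctan2(u1 * sv, np.abs(v))
                                     - np.arctan2(u2 * sv, np.abs(v)))
    return hx, hy


def _sheet_jacobian(x, y, a, b, sigma):
    """Spatial Jacobian dH_i/dx_j of :func:`_sheet_field` (local frame)."""
    dhx_dx = np.zeros_like(x)
    dhx_dy = np.zeros_like(x)
    for y0, q in ((b, sigma), (-b, -sigma)):
        u1 = x + a
        u2 = x - a
        v = y - y0
        r1 = u1 * u1 + v * v
        r2 = u2 * u2 + v * v
        dhx_dx = dhx_dx + q / (2 * np.pi) * (u1 / r1 - u2 / r2)
        dhx_dy = dhx_dy + q / (2 * np.pi) * (v / r1 - v / r2)
    # curl-free and divergence-free exterior field
    return dhx_dx, dhx_dy, dhx_dy, -dhx_dx


def _as_magnet_list(magnet) -> list[MagnetSpec]:
    if isinstance(magnet, MagnetSpec):
        return [magnet]
    return list(magnet)


def _h_field(magnets, x, y, check_interior=True):
    """Vectorized H at points (x, y); superposition over sources."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hx = np.zeros(np.broadcast(x, y).shape)
    hy = np.zeros_like(hx)
    for m in _as_magnet_list(magnets):
        F = m._frame
        px = x - m.center[0]
        py = y - m.center[1]
        lx = F[0, 0] * px + F[0, 1] * py
        ly = F[1, 0] * px + F[1, 1] * py
        if check_interior:
            inside = (np.abs(lx) < m.width / 2) & (np.abs(ly) < m.height / 2)
            if np.any(inside):
                raise MagnetDomainError(
                    "field requested inside magnet body "
                    f"(centre {m.center}, {m.width} x {m.height} m)")
        sigma = m.b_rem / MU0
        hlx, hly = _sheet_field(lx, ly, m.width / 2, m.height / 2, sigma)
        # rotate back: H_global = F.T @ H_local
        hx = hx + F[0, 0] * hlx + F[1, 0] * hly
        hy = hy + F[0, 1] * hlx + F[1, 1] * hly
    return hx, hy


def _h_jacobian(magnets, x, y):
    """Vectorized Jacobian of H in the global frame."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    jxx = np.zeros(np.broadcast(x, y).shape)
    jxy = np.zeros_like(jxx)
    jyx = np.zeros_like(jxx)
    jyy = np.zeros_like(jxx)
    for m in _as_magnet_list(magnets):
        F = m._frame
        px = x - m.center[0]
        py = y - m.center[1]
        lx = F[0, 0] * px + F[0, 1] * py
        ly = F[1, 0] * px + F[1, 1] * py
        sigma = m.b_rem / MU0
        a, b = m.width / 2, m.height / 2
        lxx, lxy, lyx, lyy = _sheet_jacobian(lx, ly, a, b, sigma)
        # J_global = F.T @ J_local @ F
        R = F.T
        for i in range(2):
            for j in range(2):
                jl = ((R[i, 0] * lxx + R[i, 1] * lyx),
                      (R[i, 0] * lxy + R[i, 1] * lyy))
                val = jl[0] * F[0, j] + jl[1] * F[1, j]
                if i == 0 and j == 0:
                    jxx = jxx + val
                elif i == 0:
                    jxy = jxy + val
                elif j == 0:
                    jyx = jyx + val
                else:
                    jyy = jyy + val
    return jxx, jxy, jyx, jyy


def _grad_h2(magnets, x, y):
    """grad |H|^2 = 2 J^T H, vectorized, global frame.

    For a single magnet the computation runs entirely in the magnet frame
    (|H|^2 is rotation invariant, so its gradient rotates as a vector),
    sharing the sheet denominators between H and its Jacobian.  For several
    sources the cross terms require the global H and Jacobian.
    """
    mags = _as_magnet_list(magnets)
    if len(mags) == 1:
        m = mags[0]
        F = m._frame
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        px = x - m.center[0]
        py = y - m.center[1]
        lx = F[0, 0] * px + F[0, 1] * py
        ly = F[1, 0] * px + F[1, 1] * py
        a, b = m.width / 2, m.height / 2
        sigma = m.b_rem / MU0
        shape = np.broadcast(lx, ly).shape
        hx = np.zeros(shape)
        hy = np.zeros(shape)
        jA = np.zeros(shape)   # dHx/dx = -dHy/dy
        jB = np.zeros(shape)   # dHx/dy = dHy/dx
        u1 = lx + a
        u2 = lx - a
        for y0, q in ((b, sigma), (-b, -sigma)):
            v = ly - y0
            r1 = u1 * u1 + v * v
            r2 = u2 * u2 + v * v
            c = q / (2 * np.pi)
            hx += c * 0.5 * (np.log(r1) - np.log(r2))
            sv = np.sign(v)
            av = np.abs(v)
            hy += c * (np.arctan2(u1 * sv, av) - np.arctan2(u2 * sv, av))
            jA += c * (u1 / r1 - u2 / r2)
            jB += c * (v / r1 - v / r2)
        glx = 2.0 * (hx * jA + hy * jB)
        gly = 2.0 * (hx * jB - hy * jA)
        gx = F[0, 0] * glx + F[1, 0] * gly
        gy = F[0, 1] * glx + F[1, 1] * gly
        return gx, gy
    hx, hy = _h_field(mags, x, y, check_interior=False)
    jxx, jxy, jyx, jyy = _h_jacobian(mags, x, y)
    gx = 2.0 * (hx * jxx + hy * jyx)
    gy = 2.0 * (hx * jxy + hy * jyy)
    return gx, gy


def field_at(magnet, point, chi: float = 0.0) -> FieldSample:
    """Sample B, H, and grad|H|^2 of one or more magnets at an exterior point.

    Parameters
    ----------
    magnet : MagnetSpec or sequence of MagnetSpec
        The field sources (superposition applies).
    point : 2-sequence of float
        Sample position, m.  Must lie outside every magnet rectangle.
    chi : float
        Volume susceptibility of the medium at the sample point (e.g. blood,
        -6.6e-7); B = mu0 (1 + chi) H.

    Raises
    ------
    MagnetDomainError
        If the point lies inside a magnet body.
    """
    x, y = float(point[0]), float(point[1])
    hx, hy = _h_field(magnet, x, y)
    gx, gy = _grad_h2(magnet, x, y)
    H = np.array([float(hx), float(hy)])
    B = MU0 * (1.0 + chi) * H
    return FieldSample(position=(x, y), B=B, H=H,
                       grad_H2=np.array([float(gx), float(gy)]))


def grad_h2_at(magnet, point) -> np.ndarray:
    """Analytic gradient of |H|^2 at an exterior point, A^2/m^3."""
    x, y = float(point[0]), float(point[1])
    # reuse interior check of the field evaluation
    _h_field(magnet, x, y)
    gx, gy = _grad_h2(magnet, x, y)
    return np.array([float(gx), float(gy)])


def _b_and_gradb(magnet: MagnetSpec, point) -> tuple[float, float]:
    """(|B|, |grad|B||) at a point; |grad|B|| = mu0 |grad|H|^2| / (2|H|)."""
    s = field_at(magnet, point)
    habs = float(np.hypot(*s.H))
    if habs == 0.0:
        return 0.0, 0.0
    gradb = MU0 * float(np.hypot(*s.grad_H2)) / (2.0 * habs)
    return float(np.hypot(*s.B)), gradb


def _placed(magnet: MagnetSpec, target, standoff: float, b_rem: float) -> MagnetSpec:
    """Magnet moved along its axis so its near face is `standoff` from target."""
    ax = np.asarray(magnet.axis, dtype=float)
    t = np.asarray(target, dtype=float)
    center = t - ax * (standoff + magnet.height / 2.0)
    return replace(magnet, center=(float(center[0]), float(center[1])),
                   b_rem=b_rem)


def calibrate_to_target(magnet: MagnetSpec, target_point, b_target: float,
                        grad_target: float, *, rel_tol_b: float = 0.01,
                        rel_tol_grad: float = 0.05) -> MagnetSpec:
    """Place and scale a magnet so it reproduces target |B| and |grad|B||.

    Solves a two-parameter problem: the stand-off distance (magnet face to
    target point, along the magnetization axis) sets the gradient-to-field
    ratio, and the remanence B_rem then scales |B| linearly.  The magnet
    cross-section is kept fixed.  Deterministic.

    Raises
    ------
    CalibrationError
        If no stand-off meets the ratio, if the required B_rem exceeds the
        validation guard, or if the resulting exterior field strength would
        exceed the 2 T source cap.  The error carries the best achievable
        values.
    """
    if b_target <= 0 or grad_target <= 0:
        raise ValueError("b_target and grad_target must be positive")

    # fixed point: already within tolerance
    try:
        b0, g0 = _b_and_gradb(magnet, target_point)
        if (abs(b0 - b_target) <= rel_tol_b * b_target
                and abs(g0 - grad_target) <= rel_tol_grad * grad_target):
            return magnet
    except MagnetDomainError:
        pass

    ratio_target = grad_target / b_target
    L = max(magnet.width, magnet.height)

    def ratio(s):
        b, g = _b_and_gradb(_placed(magnet, target_point, s, 1.0), target_point)
        return g / b

    svals = np.geomspace(1e-3 * L, 50 * L, 400)
    rvals = np.array([ratio(s) for s in svals])
    diffs = rvals - ratio_target

    from scipy.optimize import brentq

    candidates = []
    for i in range(len(svals) - 1):
        if diffs[i] == 0.0:
            candidates.append(svals[i])
        elif diffs[i] * diffs[i + 1] < 0:
            candidates.append(brentq(lambda s: ratio(s) - ratio_target,
                                     svals[i], svals[i + 1], xtol=1e-12))

    best = None
    # fallback report: closest-ratio placement at the remanence guard
    i_best = int(np.argmin(np.abs(diffs)))
    b1, _ = _b_and_gradb(_placed(magnet, target_point, svals[i_best], 1.0),
                         target_point)
    best_vals = _b_and_gradb(
        _placed(magnet, target_point, svals[i_best],
                min(b_target / b1, B_REM_MAX)), target_point)
    for s in candidates:
        b1, _ = _b_and_gradb(_placed(magnet, target_point, s, 1.0), target_point)
        b_rem = b_target / b1
        if best is None or b_rem < best[1]:
            spec = _placed(magnet, target_point, s, min(b_rem, B_REM_MAX))
            best = (s, b_rem)
            best_vals = _b_and_gradb(spec, target_point)
        if b_rem > B_REM_MAX:
            continue
        spec = _placed(magnet, target_point, s, b_rem)
        # source-strength cap: strongest exterior field is at the face centre
        face = (np.asarray(target_point, float)
                - np.asarray(magnet.axis, float) * (s * 1e-3))
        b_face, _ = _b_and_gradb(spec, face)
        if b_face > B_FIELD_MAX:
            continue
        b_got, g_got = _b_and_gradb(spec, target_point)
        if (abs(b_got - b_target) <= rel_tol_b * b_target
                and abs(g_got - grad_target) <= rel_tol_grad * grad_target):
            return spec

    raise CalibrationError(
        f"cannot reach |B|={b_target} T with |grad B|={grad_target} T/m for a "
        f"{magnet.width:g} x {magnet.height:g} m magnet under the source caps; "
        f"best achievable |B|={best_vals[0]:.4g} T, "
        f"|grad B|={best_vals[1]:.4g} T/m",
        best_b=best_vals[0], best_grad=best_vals[1])


def export_field_grid(magnet, xs: Sequence[float], ys: Sequence[float],
                      path) -> None:
    """Write a regular-grid field sample as CSV (x, y, Bx, By, Bmag).

    Points inside a magnet body are written as NaN.
    """
    import pandas as pd

    X, Y = np.meshgrid(np.asarray(xs, float), np.asarray(ys, float))
    hx, hy = _h_field(magnet, X.ravel(), Y.ravel(), check_interior=False)
    bx, by = MU0 * hx, MU0 * hy
    inside = np.zeros(X.size, dtype=bool)
    for m in _as_magnet_list(magnet):
        inside |= np.array([m.contains((px, py))
                            for px, py in zip(X.ravel(), Y.ravel())])
    bx = np.where(inside, np.nan, bx)
    by = np.where(inside, np.nan, by)
    df = pd.DataFrame({"x": X.ravel(), "y": Y.ravel(), "Bx": bx, "By": by,
                       "Bmag": np.hypot(bx, by)})
    df.to_csv(path, index=False)
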