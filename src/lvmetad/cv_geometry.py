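"""The parabolic-solid localized volume and its collective variables.

The ligand (guest) position is expressed in the host frame through
three collective variables:

* ρ — distance between the guest centre of mass and a reference point
  of the host (host COM by default, configurable);
* τ — dimensionless transverse coordinate relative to the paraboloid
  r_perp² = k·(a − a0) about the volume axis: τ = r_perp/√(k·(a − a0)),
  so τ = 1 on the paraboloid surface and τ < 1 inside;
* θ — azimuth of the transverse projection about the axis, measured in
  the plane perpendicular to the axis from a deterministic reference
  direction (for axis = +x this is +y, with +z at θ = +π/2), wrapped to
  (−π, π].

Half-harmonic walls on ρ and τ confine the guest to the volume; an
additional half-harmonic axial wall below a_min keeps the axial
coordinate away from the paraboloid apex, where τ and its gradient are
singular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import GeometryError, ParameterError
from .toy_systems import ModelPotential

__all__ = [
    "VolumeSpec",
    "CVTriple",
    "compute_cvs",
    "invert_cvs",
    "cv_gradients",
    "wall_energy",
    "wall_gradient_cvs",
    "axial_wall_energy",
    "restraint_potential",
    "wrap_angle",
]

#: guest axial coordinate must exceed a0 by at least this much (Å)
AXIAL_EPS = 1e-9
#: regularization length for the on-axis ∂θ/∂r singularity (Å);
#: |∂θ/∂r| is capped at 1/THETA_REG_LENGTH
THETA_REG_LENGTH = 0.1
#: axial clamp used when evaluating the τ wall below a_min (Å)
TAU_CLAMP_MARGIN = 0.25


def wrap_angle(theta):
    """Wrap angle(s) into (−π, π]."""
    if np.ndim(theta) == 0:
        t = (float(theta) + np.pi) % (2.0 * np.pi) - np.pi
        return np.pi if t == -np.pi else t
    t = np.mod(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(t == -np.pi, np.pi, t)


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry and stiffness of the parabolic-solid restraint.

    ``steepness`` k has units of Å (the paraboloid is r_perp² =
    k·(a − a0)); ``a0`` is the apex offset along the axis from
    ``origin``; ``a_min`` (default a0 + 0.5 Å) is where the axial
    safety wall engages.  ``wall_k`` applies to all three walls, in
    kcal/mol per squared CV unit.
    """

    origin: np.ndarray
    axis: np.ndarray
    steepness: float
    a0: float
    rho_max: float
    tau_max: float
    wall_k: float
    a_min: float | None = None

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-12:
            axis = axis / n
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis)
        if self.steepness <= 0:
            raise ParameterError("steepness k must be > 0")
        if self.rho_max <= 0 or self.tau_max <= 0 or self.wall_k <= 0:
            raise ParameterError("rho_max, tau_max, wall_k must all be > 0")
        if self.a_min is None:
            object.__setattr__(self, "a_min", self.a0 + 0.5)
        elif self.a_min <= self.a0:
            raise ParameterError("a_min must exceed a0")

    def transverse_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal (e1, e2) spanning the plane ⟂ axis.

        e1 is the normalized projection of the world axis least aligned
        with the volume axis; e2 = axis × e1.  For axis = +x this gives
        e1 = +y, e2 = +z.  Cached after the first call.
        """
        cached = getattr(self, "_basis", None)
        if cached is not None:
            return cached
        pick = int(np.argmin(np.abs(self.axis)))
        trial = np.zeros(3)
        trial[pick] = 1.0
        e1 = trial - np.dot(trial, self.axis) * self.axis
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(self.axis, e1)
        object.__setattr__(self, "_basis", (e1, e2))
        return e1, e2


@dataclass(frozen=True)
class CVTriple:
    """One (ρ, τ, θ) point; θ is wrapped to (−π, π] on construction."""

    rho: float
    tau: float
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "theta", wrap_angle(self.theta))

    def as_array(self) -> np.ndarray:
        return np.array([self.rho, self.tau, self.theta])


def _frame(guest_com, host_com, vol: VolumeSpec):
    r = np.asarray(guest_com, dtype=float) - vol.origin
    a = float(np.dot(r, vol.axis))
    r_perp = r - a * vol.axis
    return r, a, r_perp


def compute_cvs(guest_com, host_com, vol: VolumeSpec) -> CVTriple:
    """Map a Cartesian guest position to (ρ, τ, θ).

    Raises GeometryError when the axial coordinate a ≤ a0 + ε, where τ
    is undefined (the axial wall is meant to prevent this).  On the
    axis θ is taken as 0 by convention.
    """
    _, a, r_perp = _frame(guest_com, host_com, vol)
    if a <= vol.a0 + AXIAL_EPS:
        raise GeometryError(
            f"axial coordinate a={a:.6g} <= a0+eps={vol.a0 + AXIAL_EPS:.6g}: "
            "guest behind the paraboloid apex (is the axial wall configured?)"
        )
    rho = float(np.linalg.norm(np.asarray(guest_com, dtype=float) - np.asarray(host_com, dtype=float)))
    rp = float(np.linalg.norm(r_perp))
    tau = rp / np.sqrt(vol.steepness * (a - vol.a0))
    if rp < 1e-12:
        theta = 0.0
    else:
        e1, e2 = vol.transverse_basis()
        theta = float(np.arctan2(np.dot(r_perp, e2), np.dot(r_perp, e1)))
    return CVTriple(rho=rho, tau=tau, theta=theta)


def invert_cvs(cvs: CVTriple, host_com, vol: VolumeSpec, a_hi: float | None = None) -> np.ndarray:
    """Cartesian point mapping back to ``cvs`` (test oracle of compute_cvs).

    The (τ, θ) pair fixes a ray a ↦ origin + a·axis + τ√(k(a−a0))·u(θ);
    ρ selects the intersection of that ray with the host-centred sphere.
    When the sphere cuts the ray more than once the root with the
    largest axial coordinate is returned (documented tie-break).
    """
    if cvs.tau < 0 or cvs.tau > vol.tau_max:
        raise GeometryError(f"tau={cvs.tau:.6g} outside [0, tau_max={vol.tau_max:.6g}]")
    if cvs.rho < 0 or cvs.rho > vol.rho_max:
        raise GeometryError(f"rho={cvs.rho:.6g} outside [0, rho_max={vol.rho_max:.6g}]")
    host = np.asarray(host_com, dtype=float)
    e1, e2 = vol.transverse_basis()
    u = np.cos(cvs.theta) * e1 + np.sin(cvs.theta) * e2
    if a_hi is None:
        a_hi = vol.a0 + vol.rho_max + float(np.linalg.norm(vol.origin - host)) + 1.0

    def point(a):
        return vol.origin + a * vol.axis + cvs.tau * np.sqrt(vol.steepness * (a - vol.a0)) * u

    def f(a):
        return float(np.linalg.norm(point(a) - host)) - cvs.rho

    a_lo = vol.a0 + max(AXIAL_EPS, 1e-12 * max(1.0, abs(vol.a0)))
    grid = np.linspace(a_lo, a_hi, 512)
    vals = np.array([f(a) for a in grid])
    sign_change = np.nonzero(np.signbit(vals[:-1]) != np.signbit(vals[1:]))[0]
    if len(sign_change) == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if len(exact):
            return point(grid[exact[-1]])
        raise GeometryError(
            f"no axial intersection for rho={cvs.rho:.6g}, tau={cvs.tau:.6g} within bounds"
        )
    i = sign_change[-1]  # largest-a root
    a_star = brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
    return point(a_star)


def cv_gradients(guest_com, host_com, vol: VolumeSpec):
    """Analytic Cartesian gradients (∂ρ/∂r, ∂τ/∂r, ∂θ/∂r) of the CVs.

    On the axis, ∂τ/∂r is taken as the axial part only and ∂θ/∂r is
    regularized by replacing r_perp² with max(r_perp², ℓ²) with
    ℓ = THETA_REG_LENGTH, capping its magnitude at 1/ℓ.
    """
    guest = np.asarray(guest_com, dtype=float)
    host = np.asarray(host_com, dtype=float)
    _, a, r_perp = _frame(guest, host, vol)
    if a <= vol.a0 + AXIAL_EPS:
        raise GeometryError(f"axial coordinate a={a:.6g} <= a0: CV gradients undefined")

    diff = guest - host
    rho = np.linalg.norm(diff)
    grad_rho = diff / rho if rho > 1e-12 else np.zeros(3)

    s = np.sqrt(vol.steepness * (a - vol.a0))
    rp = np.linalg.norm(r_perp)
    tau = rp / s
    rp_hat = r_perp / rp if rp > 1e-12 else np.zeros(3)
    grad_tau = rp_hat / s - 0.5 * tau / (a - vol.a0) * vol.axis

    e1, e2 = vol.transverse_basis()
    v1 = np.dot(r_perp, e1)
    v2 = np.dot(r_perp, e2)
    denom = max(rp * rp, THETA_REG_LENGTH**2)
    grad_theta = (v1 * e2 - v2 * e1) / denom
    return grad_rho, grad_tau, grad_theta


def cvs_and_gradients(guest_com, host_com, vol: VolumeSpec):
    """Fused (CVTriple, ∂ρ/∂r, ∂τ/∂r, ∂θ/∂r, a) for the run loop.

    Same results as :func:`compute_cvs` + :func:`cv_gradients` but the
    shared geometry is computed once and in scalar arithmetic (this is
    the per-step hot path); ``a`` is the axial coordinate (needed for
    the axial wall).
    """
    gx, gy, gz = (float(v) for v in guest_com)
    ox, oy, oz = vol.origin
    ax, ay, az = vol.axis
    rx, ry, rz = gx - ox, gy - oy, gz - oz
    a = rx * ax + ry * ay + rz * az
    if a <= vol.a0 + AXIAL_EPS:
        raise GeometryError(
            f"axial coordinate a={a:.6g} <= a0+eps: guest behind the paraboloid apex"
        )
    px, py, pz = rx - a * ax, ry - a * ay, rz - a * az
    rp2 = px * px + py * py + pz * pz
    rp = math.sqrt(rp2)
    s = math.sqrt(vol.steepness * (a - vol.a0))
    tau = rp / s

    hx, hy, hz = (float(v) for v in host_com)
    dx, dy, dz = gx - hx, gy - hy, gz - hz
    rho = math.sqrt(dx * dx + dy * dy + dz * dz)
    if rho > 1e-12:
        grad_rho = np.array([dx / rho, dy / rho, dz / rho])
    else:
        grad_rho = np.zeros(3)

    axis = vol.axis
    coef = 0.5 * tau / (a - vol.a0)
    if rp > 1e-12:
        inv = 1.0 / (rp * s)
        grad_tau = np.array(
            [px * inv - coef * ax, py * inv - coef * ay, pz * inv - coef * az]
        )
    else:
        grad_tau = -coef * axis

    e1, e2 = vol.transverse_basis()
    v1 = px * e1[0] + py * e1[1] + pz * e1[2]
    v2 = px * e2[0] + py * e2[1] + pz * e2[2]
    theta = 0.0 if rp < 1e-12 else math.atan2(v2, v1)
    denom = max(rp2, THETA_REG_LENGTH**2)
    grad_theta = (v1 * e2 - v2 * e1) / denom
    return CVTriple(rho=rho, tau=tau, theta=theta), grad_rho, grad_tau, grad_theta, a


def wall_energy(cvs: CVTriple, vol: VolumeSpec) -> float:
    """Half-harmonic confinement energy in CV space (kcal/mol).

    wall_k·(ρ−ρ_max)² beyond ρ_max plus wall_k·(τ−τ_max)² beyond τ_max;
    zero inside; θ is periodic and unbounded.
    """
    e = 0.0
    if cvs.rho > vol.rho_max:
        e += vol.wall_k * (cvs.rho - vol.rho_max) ** 2
    if cvs.tau > vol.tau_max:
        e += vol.wall_k * (cvs.tau - vol.tau_max) ** 2
    return e


def wall_gradient_cvs(cvs: CVTriple, vol: VolumeSpec) -> tuple[float, float, float]:
    """(∂W/∂ρ, ∂W/∂τ, ∂W/∂θ) of :func:`wall_energy`; ∂W/∂θ ≡ 0."""
    d_rho = 2.0 * vol.wall_k * (cvs.rho - vol.rho_max) if cvs.rho > vol.rho_max else 0.0
    d_tau = 2.0 * vol.wall_k * (cvs.tau - vol.tau_max) if cvs.tau > vol.tau_max else 0.0
    return d_rho, d_tau, 0.0


def axial_wall_energy(a: float, vol: VolumeSpec) -> tuple[float, float]:
    """(energy, dE/da) of the half-harmonic axial wall below a_min."""
    if a < vol.a_min:
        d = a - vol.a_min
        return vol.wall_k * d * d, 2.0 * vol.wall_k * d
    return 0.0, 0.0


def restraint_potential(vol: VolumeSpec, host_com, bounds: np.ndarray | None = None) -> ModelPotential:
    """The full restraint (ρ, τ and axial walls) as a Cartesian potential.

    Vectorized over positions so the quadrature oracle can integrate
    e^(−βU) of host potential + restraint on a grid.  Below the axial
    clamp a0 + TAU_CLAMP_MARGIN the τ wall is evaluated at the clamped
    axial coordinate (the axial wall dominates there anyway).
    """
    host = np.asarray(host_com, dtype=float)
    if bounds is None:
        half = vol.rho_max + 2.0
        bounds = np.array([[-half, half]] * 3) + host[:, None]

    e1, e2 = vol.transverse_basis()

    def cv_fields(x):
        x = np.asarray(x, dtype=float)
        r = x - vol.origin
        a = r @ vol.axis
        r_perp = r - a[..., None] * vol.axis
        rp = np.linalg.norm(r_perp, axis=-1)
        a_cl = np.maximum(a, vol.a0 + TAU_CLAMP_MARGIN)
        tau = rp / np.sqrt(vol.steepness * (a_cl - vol.a0))
        rho = np.linalg.norm(x - host, axis=-1)
        return r_perp, a, a_cl, rp, tau, rho

    def energy(x):
        _, a, _, _, tau, rho = cv_fields(x)
        e = np.where(rho > vol.rho_max, vol.wall_k * (rho - vol.rho_max) ** 2, 0.0)
        e = e + np.where(tau > vol.tau_max, vol.wall_k * (tau - vol.tau_max) ** 2, 0.0)
        e = e + np.where(a < vol.a_min, vol.wall_k * (a - vol.a_min) ** 2, 0.0)
        return e

    def gradient(x):
        x = np.asarray(x, dtype=float)
        r_perp, a, a_cl, rp, tau, rho = cv_fields(x)
        g = np.zeros_like(x)
        # rho wall
        over = rho > vol.rho_max
        if np.any(over):
            diff = x - host
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(rho[..., None] > 1e-12, diff / np.maximum(rho, 1e-12)[..., None], 0.0)
            g = g + np.where(
                over[..., None], (2.0 * vol.wall_k * (rho - vol.rho_max))[..., None] * unit, 0.0
            )
        # tau wall (chain rule; axial part suppressed in the clamped zone)
        over_t = tau > vol.tau_max
        if np.any(over_t):
            s = np.sqrt(vol.steepness * (a_cl - vol.a0))
            rp_hat = np.where(rp[..., None] > 1e-12, r_perp / np.maximum(rp, 1e-12)[..., None], 0.0)
            grad_tau = rp_hat / s[..., None]
            axial_part = np.where(a > vol.a0 + TAU_CLAMP_MARGIN, 0.5 * tau / (a_cl - vol.a0), 0.0)
            grad_tau = grad_tau - axial_part[..., None] * vol.axis
            g = g + np.where(
                over_t[..., None], (2.0 * vol.wall_k * (tau - vol.tau_max))[..., None] * grad_tau, 0.0
            )
        # axial wall
        below = a < vol.a_min
        if np.any(below):
            g = g + np.where(below[..., None], (2.0 * vol.wall_k * (a - vol.a_min))[..., None] * vol.axis, 0.0)
        return g

    return ModelPotential(name="lv_restraint", dim=3, energy=energy, gradient=gradient, bounds=bounds)
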