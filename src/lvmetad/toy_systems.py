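"""Model potentials, Langevin dynamics and brute-force free-energy oracles.

This module provides the desk-scale stand-ins for a solvated
protein-ligand system: a 1D double well (the classic two-state fixture)
and a 3D host-guest model in which a rigid arrangement of attractive
sites plays the host and a point particle plays the guest.  All
quantitative claims made elsewhere in the package are checked against
:func:`reference_free_energy`, a deterministic grid quadrature of the
Boltzmann integral that knows nothing about sampling or bias.

Units: Å, ps, amu, K, kcal/mol (see :mod:`lvmetad.constants`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .constants import KB_KCAL_MOL_K, KCAL_PER_AMU_A2_PS2
from .errors import ConfigError, IntegrationError, ParameterError, RegionError

__all__ = [
    "ModelPotential",
    "HostSite",
    "HostGuestModel",
    "LangevinParams",
    "LangevinState",
    "BoxRegion",
    "RadialShellRegion",
    "make_double_well",
    "make_host_guest",
    "sum_potentials",
    "init_langevin_state",
    "langevin_step",
    "run_langevin",
    "reference_free_energy",
]


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPotential:
    """A smooth potential energy surface with analytic gradient.

    ``energy`` maps positions of shape (dim,) or (n, dim) to kcal/mol;
    ``gradient`` maps them to dU/dr of the same trailing shape
    (kcal/mol/Å).  ``bounds`` is a (dim, 2) array of closed intervals in
    Å outside which the potential is not meant to be evaluated.
    """

    name: str
    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float).reshape(self.dim, 2)
        object.__setattr__(self, "bounds", b)
        if not np.all(b[:, 1] > b[:, 0]):
            raise ParameterError("bounds must satisfy hi > lo in every dimension")

    def force(self, x: np.ndarray) -> np.ndarray:
        """-dU/dr at ``x`` (kcal/mol/Å)."""
        return -self.gradient(x)


def sum_potentials(*pots: ModelPotential, name: str | None = None) -> ModelPotential:
    """Pointwise sum of potentials sharing a dimensionality.

    Bounds are intersected; used e.g. to add restraint-wall energies on
    top of a host-guest surface before handing the total to the
    quadrature oracle.
    """
    if not pots:
        raise ParameterError("need at least one potential")
    dim = pots[0].dim
    if any(p.dim != dim for p in pots):
        raise ParameterError("potentials have mismatched dimensionality")
    lo = np.max([p.bounds[:, 0] for p in pots], axis=0)
    hi = np.min([p.bounds[:, 1] for p in pots], axis=0)

    def energy(x):
        return sum(p.energy(x) for p in pots)

    def gradient(x):
        return sum(p.gradient(x) for p in pots)

    return ModelPotential(
        name=name or "+".join(p.name for p in pots),
        dim=dim,
        energy=energy,
        gradient=gradient,
        bounds=np.stack([lo, hi], axis=1),
    )


def make_double_well(
    barrier: float,
    asymmetry: float = 0.0,
    separation: float = 4.0,
    bounds: tuple[float, float] | None = None,
) -> ModelPotential:
    """Quartic 1D double well with minima ``separation`` apart.

    U(x) = B·((x/a)² − 1)² + (asymmetry/2)·(x/a + 1) with a =
    separation/2 and B = barrier − asymmetry/2, so the saddle sits
    ``barrier`` above the lower (left) minimum up to first order in the
    tilt and the right minimum is raised by ``asymmetry``.  Free-energy
    differences between the wells are always taken from
    :func:`reference_free_energy`, never from these nominal values.
    """
    if barrier <= 0:
        raise ParameterError(f"barrier must be > 0, got {barrier}")
    if separation <= 0:
        raise ParameterError(f"separation must be > 0, got {separation}")
    quartic = barrier - 0.5 * asymmetry
    if quartic <= 0:
        raise ParameterError("asymmetry too large for the requested barrier")
    a = 0.5 * separation
    if bounds is None:
        bounds = (-separation, separation)

    def energy(x):
        x = np.asarray(x, dtype=float)
        u = x[..., 0] / a
        return quartic * (u * u - 1.0) ** 2 + 0.5 * asymmetry * (u + 1.0)

    def gradient(x):
        x = np.asarray(x, dtype=float)
        u = x[..., 0] / a
        g = quartic * 4.0 * u * (u * u - 1.0) / a + 0.5 * asymmetry / a
        return g[..., None]

    return ModelPotential(
        name=f"double_well(b={barrier:g},asym={asymmetry:g},sep={separation:g})",
        dim=1,
        energy=energy,
        gradient=gradient,
        bounds=np.array([bounds], dtype=float),
    )


# ---------------------------------------------------------------------------
# host-guest model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostSite:
    """One immobile interaction site of the toy host.

    ``kind`` is "polar" (counts toward the H-bond observable) or
    "apolar".  The site contributes an isotropic 12-6 term
    depth·((range/d)¹² − 2(range/d)⁶), minimum −depth at d = range.
    """

    position: np.ndarray
    kind: str
    well_depth: float
    range: float

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.kind not in ("polar", "apolar"):
            raise ConfigError(f"site kind must be polar/apolar, got {self.kind!r}")
        if self.range <= 0:
            raise ConfigError("site range must be > 0")


@dataclass(frozen=True)
class HostGuestModel:
    """Rigid host (sum of isotropic sites) plus a point-particle guest."""

    host_sites: tuple[HostSite, ...]
    guest_mass: float
    axis: np.ndarray
    binding_region: "RadialShellRegion"
    potential: ModelPotential

    @property
    def host_com(self) -> np.ndarray:
        """Unweighted centroid of the host sites (the ρ/d reference by default)."""
        return np.mean([s.position for s in self.host_sites], axis=0)

    def polar_sites(self) -> list[HostSite]:
        return [s for s in self.host_sites if s.kind == "polar"]


_MIN_SITE_DIST = 1e-3  # Å; clamp to keep the 12-6 core finite at the origin


def _site_energy(d, depth, rng):
    d = np.maximum(d, _MIN_SITE_DIST)
    s6 = (rng / d) ** 6
    return depth * (s6 * s6 - 2.0 * s6)


def _site_gradient_over_r(d, depth, rng):
    # dU/dd / d  (multiply by the displacement vector to get the gradient)
    d = np.maximum(d, _MIN_SITE_DIST)
    s6 = (rng / d) ** 6
    return -12.0 * depth * (s6 * s6 - s6) / (d * d)


DEFAULT_HOST_GUEST = {
    "sites": [
        {"position": [0.0, 0.0, 0.0], "kind": "apolar", "well_depth": 0.8, "range": 2.0},
        {"position": [0.9, 0.7, 0.0], "kind": "polar", "well_depth": 1.6, "range": 2.3},
        {"position": [0.9, -0.7, 0.0], "kind": "polar", "well_depth": 1.0, "range": 2.3},
    ],
    "guest_mass": 40.0,
    "axis": [1.0, 0.0, 0.0],
    "binding_region": {"r_lo": 0.0, "r_hi": 3.5},
    "bounds": 8.0,
}
"""Default toy host: an apolar core flanked by two polar sites, giving a
single attractive pocket on the +x side of the host (the volume axis)."""


def make_host_guest(config: dict | None = None) -> HostGuestModel:
    """Build the 3D host-guest model from a configuration dict.

    The config mirrors :data:`DEFAULT_HOST_GUEST`; omitted keys fall
    back to it.  The composite potential is the sum of per-site 12-6
    terms, attractive near the host and asymptotically flat, so an
    outer radial shell acts as the "solvated" reference state.
    """
    cfg = dict(DEFAULT_HOST_GUEST)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown host-guest config keys: {sorted(unknown)}")
        cfg.update(config)
    half = float(cfg["bounds"])
    sites = tuple(
        HostSite(
            position=s["position"],
            kind=s["kind"],
            well_depth=float(s["well_depth"]),
            range=float(s["range"]),
        )
        for s in cfg["sites"]
    )
    if not sites:
        raise ConfigError("host needs at least one site")
    if not any(s.kind == "polar" for s in sites):
        raise ConfigError("host needs at least one polar site (H-bond observable)")
    for s in sites:
        if np.any(np.abs(s.position) > half):
            raise ConfigError(f"site at {s.position} lies outside bounds ±{half} Å")
    axis = np.asarray(cfg["axis"], dtype=float)
    axis = axis / np.linalg.norm(axis)

    positions = np.stack([s.position for s in sites])      # (m, 3)
    depths = np.array([s.well_depth for s in sites])
    ranges = np.array([s.range for s in sites])

    site_scalars = [
        (float(p[0]), float(p[1]), float(p[2]), float(dep), float(rg))
        for p, dep, rg in zip(positions, depths, ranges)
    ]

    def energy(x):
        x = np.asarray(x, dtype=float)
        disp = x[..., None, :] - positions                  # (..., m, 3)
        d = np.linalg.norm(disp, axis=-1)
        return _site_energy(d, depths, ranges).sum(axis=-1)

    def gradient(x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:  # per-step scalar fast path
            gx = gy = gz = 0.0
            x0, x1, x2 = x
            for sx, sy, sz, dep, rg in site_scalars:
                dx, dy, dz = x0 - sx, x1 - sy, x2 - sz
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < _MIN_SITE_DIST:
                    d = _MIN_SITE_DIST
                s6 = (rg / d) ** 6
                gr = -12.0 * dep * (s6 * s6 - s6) / (d * d)
                gx += gr * dx
                gy += gr * dy
                gz += gr * dz
            return np.array([gx, gy, gz])
        disp = x[..., None, :] - positions
        d = np.linalg.norm(disp, axis=-1)
        gr = _site_gradient_over_r(d, depths, ranges)
        return (gr[..., None] * disp).sum(axis=-2)

    potential = ModelPotential(
        name="host_guest",
        dim=3,
        energy=energy,
        gradient=gradient,
        bounds=np.array([[-half, half]] * 3),
    )
    br = cfg["binding_region"]
    centroid = positions.mean(axis=0)
    binding_region = RadialShellRegion(centroid, float(br["r_lo"]), float(br["r_hi"]))
    return HostGuestModel(
        host_sites=sites,
        guest_mass=float(cfg["guest_mass"]),
        axis=axis,
        binding_region=binding_region,
        potential=potential,
    )


# ---------------------------------------------------------------------------
# regions (for the quadrature oracle and for ΔG bookkeeping)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box [lo, hi) in Cartesian space."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.atleast_1d(np.asarray(self.lo, dtype=float)))
        object.__setattr__(self, "hi", np.atleast_1d(np.asarray(self.hi, dtype=float)))

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.all((x >= self.lo) & (x < self.hi), axis=-1)


@dataclass(frozen=True)
class RadialShellRegion:
    """Spherical shell r_lo ≤ |x − center| < r_hi."""

    center: np.ndarray
    r_lo: float
    r_hi: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not 0 <= self.r_lo < self.r_hi:
            raise RegionError("need 0 <= r_lo < r_hi")

    def contains(self, x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)
        return (d >= self.r_lo) & (d < self.r_hi)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinParams:
    """Underdamped Langevin parameters (Å/ps/amu/K units)."""

    timestep: float
    friction: float
    temperature: float
    mass: float
    seed: int
    n_steps: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ParameterError("timestep must be > 0")
        if self.friction <= 0:
            raise ParameterError("friction must be > 0")
        if self.temperature < 0:
            raise ParameterError("temperature must be >= 0")
        if self.mass <= 0:
            raise ParameterError("mass must be > 0")


@dataclass
class LangevinState:
    """Mutable integrator state; ``force`` caches −∇U + f_ext at ``position``."""

    position: np.ndarray
    velocity: np.ndarray
    time: float
    step_index: int
    rng: np.random.Generator
    force: np.ndarray | None = None


def init_langevin_state(
    position: Sequence[float],
    params: LangevinParams,
    velocity: Sequence[float] | None = None,
) -> LangevinState:
    """Fresh state with its own seeded generator (same seed ⇒ same run)."""
    pos = np.atleast_1d(np.asarray(position, dtype=float))
    rng = np.random.default_rng(params.seed)
    if velocity is None:
        # Maxwell-Boltzmann draw; at T=0 this is exactly zero.
        sigma = np.sqrt(KB_KCAL_MOL_K * params.temperature * KCAL_PER_AMU_A2_PS2 / params.mass)
        vel = sigma * rng.standard_normal(pos.shape)
    else:
        vel = np.asarray(velocity, dtype=float).copy()
    return LangevinState(position=pos, velocity=vel, time=0.0, step_index=0, rng=rng)


def langevin_step(
    state: LangevinState,
    potential: ModelPotential,
    external_force: Callable[[np.ndarray], np.ndarray] | None,
    params: LangevinParams,
) -> LangevinState:
    """Advance one BAOAB step of underdamped Langevin dynamics.

    The splitting is B(dt/2) A(dt/2) O(dt) A(dt/2) B(dt/2) with the O
    part the exact Ornstein-Uhlenbeck update
    v ← c₁v + c₂ξ, c₁ = e^(−γ·dt), c₂ = √(kT/m·(1−c₁²)), ξ ~ N(0,1).
    ``external_force`` (if given) is added to −∇U — this is the hook
    through which metadynamics bias and restraint-wall forces enter.
    The state is mutated in place and returned.
    """
    dt = params.timestep
    m = params.mass
    acc = KCAL_PER_AMU_A2_PS2 / m

    def total_force(x):
        f = potential.force(x)
        if external_force is not None:
            f = f + external_force(x)
        return f

    if state.force is None:
        state.force = total_force(state.position)
    f = state.force
    # NaN/inf propagate through the sum, so one scalar check suffices
    if not math.isfinite(float(np.sum(f))):
        raise IntegrationError("non-finite force", step_index=state.step_index)

    v = state.velocity + 0.5 * dt * acc * f
    x = state.position + 0.5 * dt * v
    c1 = math.exp(-params.friction * dt)
    c2 = math.sqrt(KB_KCAL_MOL_K * params.temperature * KCAL_PER_AMU_A2_PS2 / m * (1.0 - c1 * c1))
    v = c1 * v + c2 * state.rng.standard_normal(x.shape)
    x = x + 0.5 * dt * v
    f_new = total_force(x)
    if not math.isfinite(float(np.sum(f_new))):
        raise IntegrationError("non-finite force", step_index=state.step_index + 1)
    v = v + 0.5 * dt * acc * f_new

    state.position = x
    state.velocity = v
    state.force = f_new
    state.time += dt
    state.step_index += 1
    return state


def run_langevin(
    potential: ModelPotential,
    params: LangevinParams,
    start: Sequence[float],
    external_force: Callable[[np.ndarray], np.ndarray] | None = None,
    sample_stride: int = 1,
) -> np.ndarray:
    """Integrate ``params.n_steps`` steps; return sampled positions (k, dim)."""
    state = init_langevin_state(start, params)
    out = []
    for _ in range(params.n_steps):
        langevin_step(state, potential, external_force, params)
        if state.step_index % sample_stride == 0:
            out.append(state.position.copy())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# brute-force free-energy oracle
# ---------------------------------------------------------------------------

def reference_free_energy(
    potential: ModelPotential,
    region_a,
    region_b,
    temperature: float,
    n_per_dim: int | None = None,
    full_output: bool = False,
):
    """−kT·ln(∫_a e^(−βU) / ∫_b e^(−βU)) by midpoint-rule grid quadrature.

    Deterministic and independent of any sampling machinery; this is
    the oracle every free-energy estimate in the package is tested
    against.  With ``full_output`` the Richardson-style discretization
    estimate |ΔF(h) − ΔF(2h)| is returned alongside the value.

    Regions must not overlap on the quadrature grid.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    if n_per_dim is None:
        n_per_dim = 4000 if potential.dim == 1 else 140

    def compute(n):
        axes = [
            np.linspace(lo, hi, n, endpoint=False) + 0.5 * (hi - lo) / n
            for lo, hi in potential.bounds
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        in_a = region_a.contains(pts)
        in_b = region_b.contains(pts)
        if np.any(in_a & in_b):
            raise RegionError("regions overlap on the quadrature grid")
        if not in_a.any() or not in_b.any():
            raise RegionError("a region contains no quadrature points")
        beta = 1.0 / (KB_KCAL_MOL_K * temperature)
        u = np.asarray(potential.energy(pts), dtype=float)
        u = u - u.min()  # harmless shift; cancels in the ratio
        w = np.exp(-beta * u)
        kt_ = KB_KCAL_MOL_K * temperature
        return -kt_ * (np.log(w[in_a].sum()) - np.log(w[in_b].sum()))

    value = compute(n_per_dim)
    if full_output:
        coarse = compute(max(2, n_per_dim // 2))
        return value, abs(value - coarse)
    return value
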