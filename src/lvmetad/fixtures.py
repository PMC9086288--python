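"""Fixture registry: the canonical toy study conditions.

Every quantitative demonstration in the package (tests, examples,
acceptance runs) draws its parameters from here, so the conditions are
stated once.  Magnitudes are chosen to be realistic for a desk-scale
analog of surface-pocket ligand binding:

* the 1D double well has a 5 kT barrier and 1 kT asymmetry — two
  metastable states with a thermally surmountable but rare barrier;
* the 3D host-guest pocket is ~3 kcal/mol deep (≈5 kT at 298 K),
  typical of a weak surface binder, inside a parabolic-solid volume
  whose outer shell is flat ("solvated") to within a few hundredths of
  kcal/mol;
* Langevin parameters (2 fs step, friction 2/ps, 40 amu) resolve the
  stiffest toy oscillation by ~2 orders of magnitude;
* toy metadynamics hills are narrower and lighter than the all-atom
  defaults in :mod:`lvmetad.wtmetad` because the toy CV ranges and
  barriers are smaller; γ = 8 keeps the well-tempered ceiling ≈
  (1−1/γ)·ΔF comfortably above the toy barriers.

Run lengths are the shortest for which the c(t) plateau diagnostics of
the reweighting module are flat (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .constants import kt
from .cv_geometry import VolumeSpec
from .toy_systems import (
    DEFAULT_HOST_GUEST,
    HostGuestModel,
    LangevinParams,
    ModelPotential,
    make_double_well,
    make_host_guest,
)
from .wtmetad import MetadParams

__all__ = [
    "TEMPERATURE",
    "double_well_potential",
    "double_well_walls",
    "double_well_system",
    "double_well_metad",
    "double_well_langevin",
    "host_guest_model",
    "host_guest_volume",
    "host_guest_metad",
    "host_guest_langevin",
    "HOST_GUEST_BOUND_RHO",
    "HOST_GUEST_SHELL_RHO",
    "DW_WINDOW_FRACTION",
    "HG_WINDOW_FRACTION",
]

TEMPERATURE = 298.0  # K, matching the in-vitro reference temperature

# -- 1D double well ---------------------------------------------------------

DW_BARRIER_KT = 5.0
DW_ASYMMETRY_KT = 1.0
DW_SEPARATION = 4.0          # Å between minima
DW_WALL_POS = 3.0            # Å, confining half-harmonic walls (1D analog of
                             # the localized-volume restraint)
DW_WALL_K = 20.0             # kcal/mol/Å²
DW_N_HILLS = 16000           # depositions per run
DW_WINDOW_FRACTION = 0.5     # reweight the last half of the toy run
_DW_TIMESTEP = 0.004         # ps


def double_well_potential(
    barrier_kt: float = DW_BARRIER_KT,
    asymmetry_kt: float = DW_ASYMMETRY_KT,
    separation: float = DW_SEPARATION,
    temperature: float = TEMPERATURE,
) -> ModelPotential:
    """Bare quartic double well (no confinement walls)."""
    k = kt(temperature)
    return make_double_well(barrier=barrier_kt * k, asymmetry=asymmetry_kt * k, separation=separation)


def double_well_walls(position: float = DW_WALL_POS, k: float = DW_WALL_K) -> ModelPotential:
    """Symmetric half-harmonic confinement at |x| > ``position``."""

    def energy(x):
        xx = np.asarray(x)[..., 0]
        return np.where(xx > position, k * (xx - position) ** 2, 0.0) + np.where(
            xx < -position, k * (xx + position) ** 2, 0.0
        )

    def gradient(x):
        xx = np.asarray(x, dtype=float)[..., 0]
        g = np.where(xx > position, 2 * k * (xx - position), 0.0) + np.where(
            xx < -position, 2 * k * (xx + position), 0.0
        )
        return g[..., None]

    return ModelPotential(
        name="confinement_walls", dim=1, energy=energy, gradient=gradient,
        bounds=np.array([[-6.0, 6.0]]),
    )


def double_well_system(
    barrier_kt: float = DW_BARRIER_KT,
    asymmetry_kt: float = DW_ASYMMETRY_KT,
) -> ModelPotential:
    """The confined double well the 1D study runs on: quartic + walls.

    The walls play the role the localized volume plays in 3D — they
    stop the well-tempered bias from pushing the walker far up the
    quartic wings, which caps the free-energy range the bias must fill
    and speeds convergence.  The quadrature oracle integrates this
    same total potential, so walls cancel exactly in every comparison.
    Energy and gradient are fused into single expressions (this is the
    hot path of the million-step study runs).
    """
    kT = kt(TEMPERATURE)
    barrier = barrier_kt * kT
    asym = asymmetry_kt * kT
    quartic = barrier - 0.5 * asym
    a = 0.5 * DW_SEPARATION
    wp, wk = DW_WALL_POS, DW_WALL_K

    def energy(x):
        xx = np.asarray(x, dtype=float)[..., 0]
        u = xx / a
        over = np.maximum(xx - wp, 0.0)
        under = np.maximum(-wp - xx, 0.0)
        return quartic * (u * u - 1.0) ** 2 + 0.5 * asym * (u + 1.0) + wk * (over * over + under * under)

    def gradient(x):
        xx = np.asarray(x, dtype=float)[..., 0]
        u = xx / a
        g = quartic * 4.0 * u * (u * u - 1.0) / a + 0.5 * asym / a
        g = g + 2.0 * wk * (np.maximum(xx - wp, 0.0) - np.maximum(-wp - xx, 0.0))
        return g[..., None]

    return ModelPotential(
        name="double_well_confined", dim=1, energy=energy, gradient=gradient,
        bounds=np.array([[-6.0, 6.0]]),
    )


def double_well_metad() -> MetadParams:
    """Toy 1D protocol: hills narrow enough to resolve the quartic flanks
    (σ² « kT/U'' there), heights ≈ h0 « kT, γ = 6 keeps late hills adaptive."""
    return MetadParams(h0=0.025, stride=0.5, widths=(0.15, 0.04, np.pi / 8), gamma=6.0)


def double_well_langevin(seed: int, n_hills: int = DW_N_HILLS) -> LangevinParams:
    stride_steps = int(round(double_well_metad().stride / _DW_TIMESTEP))
    return LangevinParams(
        timestep=_DW_TIMESTEP, friction=1.0, temperature=TEMPERATURE, mass=40.0,
        seed=seed, n_steps=n_hills * stride_steps,
    )


# -- 3D host-guest ----------------------------------------------------------

HG_N_HILLS = 4000
HG_WINDOW_FRACTION = 0.5
HOST_GUEST_BOUND_RHO = (0.0, 3.5)    # Å from host COM: the pocket
HOST_GUEST_SHELL_RHO = (4.5, 5.5)    # Å: flat outer shell ("solvated")


def host_guest_model() -> HostGuestModel:
    return make_host_guest(DEFAULT_HOST_GUEST)


def host_guest_volume() -> VolumeSpec:
    """Paraboloid about +x with apex behind the host surface.

    steepness k = 1.5 Å opens to r_perp ≈ 3.1 Å at the far wall
    (ρ_max = 6 Å); the axial wall at a_min = 0 keeps the guest half an
    Å clear of the apex singularity.
    """
    return VolumeSpec(
        origin=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]),
        steepness=1.5, a0=-0.5, rho_max=6.0, tau_max=1.0, wall_k=10.0, a_min=0.0,
    )


def host_guest_metad() -> MetadParams:
    """Toy 3D protocol: 1 ps between hills gives the guest a couple of
    velocity-relaxation times to decorrelate between depositions, which
    keeps the quasi-static assumption of the reweighting estimator honest."""
    return MetadParams(h0=0.10, stride=1.0, widths=(0.4, 0.12, np.pi / 4), gamma=6.0)


def host_guest_langevin(seed: int, n_hills: int = HG_N_HILLS) -> LangevinParams:
    stride_steps = int(round(host_guest_metad().stride / 0.004))
    return LangevinParams(
        timestep=0.004, friction=1.0, temperature=TEMPERATURE, mass=40.0,
        seed=seed, n_steps=n_hills * stride_steps,
    )
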