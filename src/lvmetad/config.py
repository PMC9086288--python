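"""Structured run configuration (YAML) with strict schema validation.

Unknown keys are rejected outright; the keys of an all-atom MD setup
(thermostat, barostat, force field, ...) get a pointed message, since
this package simulates toy potentials only and such keys would
silently do nothing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .contacts import ContactSet, SwitchingParams
from .cv_geometry import VolumeSpec
from .errors import SchemaError
from .io import config_hash
from .toy_systems import LangevinParams, make_double_well, make_host_guest
from .wtmetad import MetadParams

__all__ = ["RunConfig", "load_config", "config_from_dict"]

#: all-atom-only keys we refuse with a targeted message
ALL_ATOM_KEYS = {
    "thermostat", "barostat", "force_field", "water_model", "pme",
    "constraints", "lincs", "annealing", "equilibration",
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemSection(_Strict):
    kind: Literal["double_well", "host_guest"]
    # double_well
    barrier: Optional[float] = None        # kcal/mol
    asymmetry: float = 0.0
    separation: float = 4.0
    # host_guest (falls back to the package default host when omitted)
    host_guest: Optional[dict] = None


class LangevinSection(_Strict):
    timestep: float = 0.002
    friction: float = 2.0
    temperature: float = 298.0
    mass: float = 40.0
    n_steps: int = 100000


class MetadSection(_Strict):
    h0: float = 0.287
    stride: float = 1.0
    widths: tuple[float, float, float] = (1.0, 0.04, float(np.pi / 8))
    gamma: float = 20.0
    colvar_stride: Optional[float] = None


class VolumeSection(_Strict):
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    steepness: float = 1.5
    a0: float = -0.5
    rho_max: float = 6.0
    tau_max: float = 1.0
    wall_k: float = 10.0
    a_min: Optional[float] = None


class SwitchingSection(_Strict):
    n: int = 8
    m: int = 12
    d0: float = 0.0
    r0: float = 2.5


class ContactsSection(_Strict):
    pairs: list[tuple[str, str]]
    params: SwitchingSection = SwitchingSection()


class ReweightSection(_Strict):
    window_fraction: float = 2.0 / 13.0   # reweight the final part of the run
    n_blocks: int = 5
    standard_volume: Optional[float] = None


class RunConfig(_Strict):
    """Top-level run description; see examples/ for YAML layouts."""

    seed: int = 0
    output_prefix: str = "lvmetad_run"
    system: SystemSection
    langevin: LangevinSection = LangevinSection()
    metad: MetadSection = MetadSection()
    volume: Optional[VolumeSection] = None
    contacts: Optional[ContactsSection] = None
    reweight: ReweightSection = ReweightSection()

    # -- builders ----------------------------------------------------------

    def build_system(self):
        if self.system.kind == "double_well":
            if self.system.barrier is None:
                raise SchemaError("double_well system needs 'barrier' (kcal/mol)")
            return make_double_well(
                barrier=self.system.barrier,
                asymmetry=self.system.asymmetry,
                separation=self.system.separation,
            )
        return make_host_guest(self.system.host_guest)

    def build_langevin(self) -> LangevinParams:
        s = self.langevin
        return LangevinParams(
            timestep=s.timestep, friction=s.friction, temperature=s.temperature,
            mass=s.mass, seed=self.seed, n_steps=s.n_steps,
        )

    def build_metad(self) -> MetadParams:
        s = self.metad
        return MetadParams(h0=s.h0, stride=s.stride, widths=tuple(s.widths), gamma=s.gamma)

    def build_volume(self) -> VolumeSpec | None:
        if self.volume is None:
            return None
        v = self.volume
        return VolumeSpec(
            origin=np.asarray(v.origin), axis=np.asarray(v.axis), steepness=v.steepness,
            a0=v.a0, rho_max=v.rho_max, tau_max=v.tau_max, wall_k=v.wall_k, a_min=v.a_min,
        )

    def build_contacts(self) -> ContactSet | None:
        if self.contacts is None:
            return None
        p = self.contacts.params
        return ContactSet(
            pairs=tuple(tuple(pair) for pair in self.contacts.pairs),
            params=SwitchingParams(n=p.n, m=p.m, d0=p.d0, r0=p.r0),
        )

    def hash(self) -> str:
        return config_hash(self.model_dump_json())


def _explain(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        key = e["loc"][-1] if e["loc"] else ""
        msg = e["msg"]
        if e["type"] == "extra_forbidden" and str(key) in ALL_ATOM_KEYS:
            msg = (
                "all-atom MD machinery (thermostats, barostats, force fields, "
                "solvation) is out of scope for this toy simulator; remove this key"
            )
        lines.append(f"  {loc}: {msg}")
    return "\n".join(lines)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise SchemaError(f"invalid run configuration:\n{_explain(err)}") from None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)
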