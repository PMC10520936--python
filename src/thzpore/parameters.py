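"""Typed, validated model configuration.

Every constant of the coupled model lives here: cell geometry, passive
membrane electrical properties, hydrophilic-pore (electroporation) constants,
the 4-state Na+,K+-ATPase cycle constants, and the transported ion species.
Two named cell-type parameter sets ship with the package
(``rat_neostriatal``, ``guinea_pig_ventricular``); their electroporation and
pump constants are literature defaults and are overridable from JSON
(canonical) or YAML (convenience) config files.

Units are SI throughout; concentrations are mol/m^3 (numerically equal to mM).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .constants import PhysicalConstants

VALID_SPECIES = ("Na", "K", "Ca", "Cl")


class ConfigError(ValueError):
    """Raised when a configuration file or bundle is invalid."""


@dataclass
class IonSpecies:
    """One transported ion species.

    Parameters
    ----------
    name : str
        One of Na, K, Ca, Cl.
    z : int
        Valence.
    D : float
        Diffusion coefficient in water, m^2/s.
    a : float
        Effective (hydrated) ion radius, m; enters the steric term of the
        generalized modified PNP flux law.
    c_i0, c_o0 : float
        Initial intracellular / extracellular concentration, mol/m^3.
    """

    name: str
    z: int
    D: float
    a: float
    c_i0: float
    c_o0: float

    def violations(self) -> list[str]:
        v = []
        if self.name not in VALID_SPECIES:
            v.append(f"species name {self.name!r} not in {VALID_SPECIES}")
        if self.z not in (-1, 1, 2):
            v.append(f"species {self.name}: valence z={self.z} not in {{-1,+1,+2}}")
        if not self.D > 0:
            v.append(f"species {self.name}: D must be > 0 (got {self.D})")
        if not self.a > 0:
            v.append(f"species {self.name}: a must be > 0 (got {self.a})")
        if self.c_i0 < 0 or self.c_o0 < 0:
            v.append(f"species {self.name}: concentrations must be >= 0")
        return v


@dataclass
class CellGeometry:
    """Spherical cell in a concentric spherical simulation domain."""

    R_cell: float = 3.3e-6  # m
    R_domain: float = 9.9e-6  # m
    d_mem: float = 5.0e-9  # m
    N_theta: int = 13  # polar-angle nodes, must contain multiples of pi/6
    N_r_in: int = 33  # radial nodes inside (incl. centre and membrane face)
    N_r_out: int = 33  # radial nodes outside (incl. membrane face and boundary)

    @property
    def A_cell(self) -> float:
        return 4.0 * math.pi * self.R_cell**2

    def theta_nodes(self):
        import numpy as np

        return np.linspace(0.0, math.pi, self.N_theta)

    def violations(self) -> list[str]:
        v = []
        if not 0 < self.R_cell < self.R_domain:
            v.append("geometry: require 0 < R_cell < R_domain")
        if not self.d_mem < 0.01 * self.R_cell:
            v.append("geometry: d_mem must be << R_cell")
        if self.N_theta < 7 or (self.N_theta - 1) % 6 != 0:
            v.append(
                "geometry: N_theta must be >= 7 with N_theta-1 divisible by 6 "
                "so theta = 0, pi/6, ..., pi are grid nodes"
            )
        if self.N_r_in < 4 or self.N_r_out < 4:
            v.append("geometry: need at least 4 radial nodes per region")
        return v


@dataclass
class MembraneElectrical:
    """Passive electrical properties of membrane and bulk media."""

    C_m: float = 1.0e-2  # F/m^2
    g1: float = 2.0  # S/m^2, lumped physiological channel conductance
    V_rest: float = -70.0e-3  # V
    sigma_i: float = 0.455  # S/m, cytoplasm
    sigma_o: float = 1.2  # S/m, extracellular saline
    T: float = 310.0  # K

    def violations(self) -> list[str]:
        v = []
        if not self.C_m > 0:
            v.append("electrical: C_m must be > 0")
        if self.g1 < 0:
            v.append("electrical: g1 must be >= 0")
        if not (self.sigma_i > 0 and self.sigma_o > 0):
            v.append("electrical: sigma_i and sigma_o must be > 0")
        if not self.T > 0:
            v.append("electrical: T must be > 0")
        return v


@dataclass
class PoreModelParams:
    """Hydrophilic-pore nucleation and radius-dynamics constants.

    Literature defaults of the asymptotic electroporation model family
    (pore-density ODE + per-pore radius ODE with area-coupled tension).
    """

    alpha: float = 1.0e9  # 1/(m^2 s), pore creation rate
    V_ep: float = 0.258  # V, characteristic electroporation voltage
    N0: float = 1.5e9  # 1/m^2, equilibrium density at Vm = 0
    r_star: float = 0.51e-9  # m, minimum pore radius
    r_m: float = 0.80e-9  # m, minimum-energy radius at Vm = 0
    q_exp: float = 2.0  # q_p = (r_m/r_star)**q_exp
    D_p: float = 5.0e-14  # m^2/s, pore-radius diffusion coefficient
    F_max: float = 0.70e-9  # N/V^2, max electric force at Vm = 1 V
    r_h: float = 0.97e-9  # m
    r_t: float = 0.31e-9  # m
    beta: float = 1.4e-19  # J, steric repulsion energy
    gamma: float = 1.8e-11  # J/m, pore edge energy
    sigma_prime: float = 2.0e-2  # N/m, hydrocarbon-water interface tension
    sigma_0: float = 1.0e-6  # N/m, bilayer tension without pores

    @property
    def q_p(self) -> float:
        return (self.r_m / self.r_star) ** self.q_exp

    def violations(self) -> list[str]:
        v = []
        for name in (
            "alpha", "V_ep", "N0", "r_star", "r_m", "q_exp", "D_p",
            "F_max", "r_h", "r_t", "beta", "gamma", "sigma_prime", "sigma_0",
        ):
            if not getattr(self, name) > 0:
                v.append(f"pore: {name} must be > 0")
        if self.r_star > self.r_m:
            v.append("pore: require r_star <= r_m")
        elif not self.q_p > 1:
            v.append("pore: q_p = (r_m/r_star)**q_exp must exceed 1")
        return v


@dataclass
class AtpaseParams:
    """4-state Na+,K+-ATPase cycle constants.

    Rate constants k1p..k4m and dissociation constants are the composite-rate
    inputs of the cycle model; ``d_*`` are the dimensionless voltage-partition
    coefficients of the ion-binding exponentials; ``F_c`` converts the
    steady-state cycle rate (1/s) into whole-cell pump current (A).
    """

    k1p: float = 1050.0  # 1/s
    k2p: float = 481.0  # 1/s
    k3p: float = 2000.0  # 1/s
    k4p: float = 320.0  # 1/s
    k1m: float = 172.1  # m^3/mol/s (times c_MgADP)
    k2m: float = 20.0  # 1/s
    k3m: float = 2.0e3  # m^6/mol^2/s (times c_P * [H+])
    k4m: float = 10.0  # 1/s
    kd_Nai0: float = 5.0  # mol/m^3
    kd_Nao0: float = 0.18  # mol/m^3
    kd_Ki0: float = 18.8  # mol/m^3
    kd_Ko0: float = 0.8  # mol/m^3
    kd_MgATP: float = 0.6  # mol/m^3
    d_Nai: float = -0.14
    d_Nao: float = 0.44
    d_Ki: float = -0.14
    d_Ko: float = 0.23
    c_MgATP: float = 6.8  # mol/m^3
    c_MgADP: float = 0.02  # mol/m^3
    c_P: float = 4.2  # mol/m^3, inorganic phosphate
    pH: float = 7.09
    F_c: float = 6.0e-12  # A s, whole-cell current per unit cycle rate

    def violations(self) -> list[str]:
        v = []
        for name in (
            "k1p", "k2p", "k3p", "k4p", "k1m", "k2m", "k3m", "k4m",
            "kd_Nai0", "kd_Nao0", "kd_Ki0", "kd_Ko0", "kd_MgATP", "F_c",
        ):
            if not getattr(self, name) > 0:
                v.append(f"atpase: {name} must be > 0")
        for name in ("c_MgATP", "c_MgADP", "c_P"):
            if getattr(self, name) < 0:
                v.append(f"atpase: {name} must be >= 0")
        return v


@dataclass
class RunFlags:
    """Model-variant switches (all documented defaults)."""

    include_pump_current_in_vm: bool = False  # pump current in the Vm balance
    clamp_extracellular: bool = False  # "infinite bath" mode
    lateral_diffusion: bool = False  # explicit theta-to-theta bulk diffusion
    power_mode: str = "per_molecule"  # or "literal" (printed /N_A form)
    negative_concentration: str = "substep"  # or "clamp"

    def violations(self) -> list[str]:
        v = []
        if self.power_mode not in ("per_molecule", "literal"):
            v.append("flags: power_mode must be 'per_molecule' or 'literal'")
        if self.negative_concentration not in ("substep", "clamp"):
            v.append("flags: negative_concentration must be 'substep' or 'clamp'")
        return v


@dataclass
class ParameterBundle:
    """Complete, validated model parameterization for one cell type."""

    cell_type: str
    geometry: CellGeometry = field(default_factory=CellGeometry)
    electrical: MembraneElectrical = field(default_factory=MembraneElectrical)
    pore: PoreModelParams = field(default_factory=PoreModelParams)
    atpase: AtpaseParams = field(default_factory=AtpaseParams)
    species: list[IonSpecies] = field(default_factory=list)
    flags: RunFlags = field(default_factory=RunFlags)
    Q_ATP_override: float | None = None

    @property
    def constants(self) -> PhysicalConstants:
        return PhysicalConstants.at_temperature(self.electrical.T, self.Q_ATP_override)

    def species_by_name(self, name: str) -> IonSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "cell_type": self.cell_type,
            "geometry": dataclasses.asdict(self.geometry),
            "electrical": dataclasses.asdict(self.electrical),
            "pore": dataclasses.asdict(self.pore),
            "atpase": dataclasses.asdict(self.atpase),
            "species": [dataclasses.asdict(s) for s in self.species],
            "flags": dataclasses.asdict(self.flags),
        }
        if self.Q_ATP_override is not None:
            d["Q_ATP_override"] = self.Q_ATP_override
        return d


def _coerce_section(cls, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"unknown key {section}.{key} ignored", stacklevel=3)
            continue
        kwargs[key] = value
    return cls(**kwargs)


def bundle_from_dict(data: dict[str, Any]) -> ParameterBundle:
    """Build a bundle from a (possibly partial) nested dict.

    A ``cell_type`` naming one of the shipped parameter sets seeds every
    section with that set's defaults; explicit sections override field-wise.
    Unknown keys warn; invalid values raise :class:`ConfigError`.
    """
    data = dict(data)
    cell_type = data.pop("cell_type", "rat_neostriatal")
    if cell_type in available_cell_types():
        base = default_bundle(cell_type).to_dict()
    else:
        base = default_bundle("rat_neostriatal").to_dict()
        base["cell_type"] = cell_type

    top_known = {"geometry", "electrical", "pore", "atpase", "species", "flags",
                 "Q_ATP_override"}
    for key, value in data.items():
        if key not in top_known:
            warnings.warn(f"unknown top-level config key {key!r} ignored", stacklevel=2)
            continue
        if key == "species":
            base_sp = {s["name"]: s for s in base["species"]}
            for sp in value:
                name = sp.get("name")
                if name in base_sp:
                    base_sp[name].update(sp)
                else:
                    base_sp[name] = sp
            base["species"] = list(base_sp.values())
        elif key == "Q_ATP_override":
            base["Q_ATP_override"] = value
        else:
            base[key].update(value)

    bundle = ParameterBundle(
        cell_type=base["cell_type"],
        geometry=_coerce_section(CellGeometry, base["geometry"], "geometry"),
        electrical=_coerce_section(MembraneElectrical, base["electrical"], "electrical"),
        pore=_coerce_section(PoreModelParams, base["pore"], "pore"),
        atpase=_coerce_section(AtpaseParams, base["atpase"], "atpase"),
        species=[_coerce_section(IonSpecies, sp, f"species[{sp.get('name')}]")
                 for sp in base["species"]],
        flags=_coerce_section(RunFlags, base.get("flags", {}), "flags"),
        Q_ATP_override=base.get("Q_ATP_override"),
    )
    problems = validate_bundle(bundle)
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return bundle


def validate_bundle(bundle: ParameterBundle) -> list[str]:
    """All invariant violations in the bundle; empty list means valid."""
    v: list[str] = []
    v += bundle.geometry.violations()
    v += bundle.electrical.violations()
    v += bundle.pore.violations()
    v += bundle.atpase.violations()
    v += bundle.flags.violations()
    names = [s.name for s in bundle.species]
    if sorted(names) != sorted(VALID_SPECIES):
        v.append(f"species: exactly the four species {VALID_SPECIES} required, got {names}")
    for s in bundle.species:
        v += s.violations()
    return v


def load_config(path: str | Path) -> ParameterBundle:
    """Load and validate a JSON or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return bundle_from_dict(data)


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a full bundle back to JSON or YAML (round-trips with load)."""
    path = Path(path)
    d = bundle.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=False) + "\n")


def available_cell_types() -> list[str]:
    root = resources.files("thzpore") / "defaults"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".json"))


def default_bundle(cell_type: str = "rat_neostriatal") -> ParameterBundle:
    """The shipped parameter set for one of the named cell types."""
    root = resources.files("thzpore") / "defaults"
    f = root / f"{cell_type}.json"
    try:
        data = json.loads(f.read_text())
    except FileNotFoundError:
        raise ConfigError(
            f"unknown cell type {cell_type!r}; available: {available_cell_types()}"
        ) from None
    # direct construction (no recursion through bundle_from_dict)
    bundle = ParameterBundle(
        cell_type=data["cell_type"],
        geometry=_coerce_section(CellGeometry, data["geometry"], "geometry"),
        electrical=_coerce_section(MembraneElectrical, data["electrical"], "electrical"),
        pore=_coerce_section(PoreModelParams, data["pore"], "pore"),
        atpase=_coerce_section(AtpaseParams, data["atpase"], "atpase"),
        species=[_coerce_section(IonSpecies, sp, "species") for sp in data["species"]],
        flags=_coerce_section(RunFlags, data.get("flags", {}), "flags"),
        Q_ATP_override=data.get("Q_ATP_override"),
    )
    problems = validate_bundle(bundle)
    if problems:  # pragma: no cover - shipped defaults are valid
        raise ConfigError("shipped default invalid:\n  " + "\n  ".join(problems))
    return bundle
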