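"""Transmembrane ion transport through open pore area.

Flux densities through the membrane use the generalized modified
Poisson-Nernst-Planck (GMPNP) law: electromigration + diffusion + a steric
term accounting for the finite effective size of hydrated ions.  Gradients
across the membrane are two-point finite differences over the membrane
thickness, the potential gradient is -Vm/d_mem, and concentrations inside
the membrane are the arithmetic mean of the two faces.  Positive flux is
directed out of the cell.

Per-angle fluxes scale with the local fractional open pore area; the pore
current density is F * sum_j z_j J_j exactly (charge-flux identity).
Concentrations live in conical-shell compartments (one intra- and one
extracellular per polar-angle node); updates conserve total moles per
species to round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants
from .parameters import CellGeometry, IonSpecies


@dataclass
class ConcentrationState:
    """Per-species, per-theta concentrations, mol/m^3.

    Arrays are shaped (n_species, N_theta); the species order is fixed by
    the bundle's species list.
    """

    c_i: np.ndarray
    c_o: np.ndarray

    @staticmethod
    def initial(species: list[IonSpecies], n_theta: int) -> "ConcentrationState":
        c_i = np.array([[s.c_i0] * n_theta for s in species], dtype=float)
        c_o = np.array([[s.c_o0] * n_theta for s in species], dtype=float)
        return ConcentrationState(c_i, c_o)


@dataclass
class FluxSet:
    """Per-species, per-theta molar pore fluxes and the pore current.

    J_pore has units mol/(m^2 s) on the membrane element (already scaled by
    the open-area fraction); I_p is the pore current density A/m^2.
    """

    J_pore: np.ndarray  # (n_species, N_theta)
    I_p: np.ndarray  # (N_theta,)


def steric_occupancy(species: list[IonSpecies], c: np.ndarray,
                     constants: PhysicalConstants) -> np.ndarray:
    """sum_j N_A a_j^3 c_j, the excluded-volume occupancy (dimensionless)."""
    a3 = np.array([s.a**3 for s in species])
    return np.tensordot(a3, c, axes=(0, 0)) * constants.N_A


def gmpnp_flux_density(
    species: list[IonSpecies],
    c_i: np.ndarray,
    c_o: np.ndarray,
    Vm,
    d_mem: float,
    T: float,
    constants: PhysicalConstants | None = None,
) -> np.ndarray:
    """GMPNP molar flux density through unit open pore area, mol/(m^2 s).

    c_i, c_o are (n_species, ...) concentrations on the two membrane faces;
    Vm broadcasts over the trailing axes.  Positive = out of the cell.
    """
    cst = constants if constants is not None else PhysicalConstants.at_temperature(T)
    c_i = np.asarray(c_i, dtype=float)
    c_o = np.asarray(c_o, dtype=float)
    c_mid = 0.5 * (c_i + c_o)

    occ = steric_occupancy(species, c_mid, cst)
    if np.any(occ >= 1.0):
        raise ValueError("steric occupancy >= 1: the GMPNP model is invalid here")

    D = np.array([s.D for s in species]).reshape(-1, *([1] * (c_mid.ndim - 1)))
    z = np.array([float(s.z) for s in species]).reshape(-1, *([1] * (c_mid.ndim - 1)))
    a3 = np.array([s.a**3 for s in species]).reshape(-1, *([1] * (c_mid.ndim - 1)))

    grad_phi = -np.asarray(Vm, dtype=float) / d_mem  # outward-normal convention
    grad_c = (c_o - c_i) / d_mem
    steric_num = np.sum(cst.N_A * a3 * grad_c, axis=0)

    J = (
        -D * c_mid * cst.F * z / (cst.R_u * T) * grad_phi
        - D * grad_c
        - D * c_mid * steric_num / (1.0 - occ)
    )
    return J


def pore_flux(
    flux_density: np.ndarray,
    fp: np.ndarray,
    species: list[IonSpecies],
    constants: PhysicalConstants,
) -> FluxSet:
    """Scale unit-area flux densities by the open-area fraction f_p per theta
    and form the pore current density from the charge-flux identity."""
    fp = np.asarray(fp, dtype=float)
    if np.any(fp > 1.0):
        raise ValueError("fractional open pore area exceeds 1")
    J = flux_density * fp  # broadcast over species axis
    z = np.array([float(s.z) for s in species]).reshape(-1, 1)
    I_p = constants.F * np.sum(z * J, axis=0)
    return FluxSet(J_pore=J, I_p=I_p)


def compartment_volumes(geometry: CellGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A_theta, V_i_theta, V_o_theta): membrane element areas and the
    conical-shell compartment volumes per theta node."""
    th = geometry.theta_nodes()
    edges = np.concatenate([[0.0], 0.5 * (th[1:] + th[:-1]), [np.pi]])
    dcos = np.cos(edges[:-1]) - np.cos(edges[1:])
    A_theta = 2.0 * np.pi * geometry.R_cell**2 * dcos
    V_i = (2.0 * np.pi / 3.0) * geometry.R_cell**3 * dcos
    V_o = (2.0 * np.pi / 3.0) * (geometry.R_domain**3 - geometry.R_cell**3) * dcos
    return A_theta, V_i, V_o


def update_concentrations(
    state: ConcentrationState,
    total_flux: np.ndarray,
    geometry: CellGeometry,
    dt: float,
    clamp_extracellular: bool = False,
    negative_policy: str = "substep",
    flux_fn=None,
    volumes=None,
) -> ConcentrationState:
    """Advance compartment concentrations under total outward fluxes.

    ``total_flux`` is mol/(m^2 s) per species per theta (pores + pump).
    Intracellular compartments lose J*A_theta*dt/V_i; extracellular gain the
    same moles (unless clamped to an infinite bath).  If a step would drive
    any concentration negative, the step is sub-divided with the flux
    recomputed via ``flux_fn(state) -> total_flux`` at each sub-step
    ("substep" policy).  As the final guarantee (and as the whole "clamp"
    policy) the moles moved out of any compartment are limited to the moles
    it holds: the mid-membrane mean concentration in the flux law keeps an
    outward flux finite even as the source face empties, so a limiter is
    required; unlike clamping concentrations at zero, limiting the transfer
    conserves mass exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    A_theta, V_i, V_o = compartment_volumes(geometry) if volumes is None else volumes

    def advance(st: ConcentrationState, flux, h, limit=False) -> ConcentrationState:
        moles = flux * A_theta * h  # mol leaving each inner compartment
        if limit:
            avail_out = st.c_i * V_i  # moles available for outward transfer
            avail_in = st.c_o * V_o
            moles = np.minimum(moles, avail_out)
            moles = np.maximum(moles, -avail_in)
        c_i2 = st.c_i - moles / V_i
        c_o2 = st.c_o if clamp_extracellular else st.c_o + moles / V_o
        return ConcentrationState(c_i2, c_o2)

    out = advance(state, total_flux, dt)
    if np.all(out.c_i >= 0) and np.all(out.c_o >= 0):
        return out

    if negative_policy == "substep" and flux_fn is not None:
        nsub = 2
        while nsub <= 256:
            h = dt / nsub
            cur = state
            ok = True
            for _ in range(nsub):
                cur = advance(cur, flux_fn(cur), h)
                if np.any(cur.c_i < 0) or np.any(cur.c_o < 0):
                    ok = False
                    break
            if ok:
                return cur
            nsub *= 2

    warnings.warn(
        "outgoing flux limited to the moles available in a compartment",
        RuntimeWarning, stacklevel=2,
    )
    return advance(state, total_flux, dt, limit=True)


def total_moles(state: ConcentrationState, geometry: CellGeometry) -> np.ndarray:
    """Per-species total moles (intra + extra, summed over theta)."""
    _, V_i, V_o = compartment_volumes(geometry)
    return np.sum(state.c_i * V_i, axis=1) + np.sum(state.c_o * V_o, axis=1)


def average_unweighted(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain arithmetic mean over theta nodes (NOT solid-angle weighted).

    This is the angular average used for whole-cell summary traces.
    """
    return np.mean(series, axis=axis)
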