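"""Hydrophilic-pore (electroporation) dynamics.

The asymptotic electroporation model tracks, per polar angle, a pore number
density N(t, theta) obeying a creation/resealing ODE driven by exp((Vm/V_ep)^2),
and the radii of the created pores, each obeying an overdamped force-balance
ODE (electric force, steric repulsion, edge energy, membrane tension).  The
tension is reduced by the total open pore area of the whole cell, coupling
pores everywhere on the membrane.

Pores are represented deterministically as *cohorts*: a cohort is a group of
pores at one angle sharing a radius and a (possibly fractional) count.  New
pores are born at the minimum radius r* and merge into the youngest cohort
(the "nursery"); a fresh nursery slot opens every few steps, and when an
angle exhausts its slot budget the two nearest-radius cohorts merge at the
area-preserving radius.  Negative density increments scale all cohort counts
down proportionally, so the density and the cohort sum stay consistent
exactly.  The model is a deterministic density description: runs are
reproducible bit-for-bit at fixed step sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants
from .parameters import PoreModelParams

#: cap on (|Vm|/V_ep)^2 inside exponentials; at V_ep ~ 0.26 V this engages
#: near |Vm| ~ 3.6 V, far beyond any membrane potential the model supports
VSQ_CLAMP = 200.0

MAX_COHORTS = 64  # slots per theta node; nearest-radius merge beyond this
PROMOTE_EVERY = 16  # steps between opening a fresh nursery cohort


def _vsq(Vm, V_ep: float):
    x = (np.asarray(Vm, dtype=float) / V_ep) ** 2
    return np.minimum(x, VSQ_CLAMP)


def equilibrium_density(Vm, params: PoreModelParams):
    """Equilibrium pore density N_eq(Vm) = N0 exp(q_p (Vm/V_ep)^2), 1/m^2."""
    out = params.N0 * np.exp(np.minimum(params.q_p * _vsq(Vm, params.V_ep), VSQ_CLAMP * 2))
    return out if np.ndim(out) else float(out)


def density_rate(N, Vm, params: PoreModelParams):
    """dN/dt = alpha exp((Vm/V_ep)^2) (1 - N/N_eq(Vm)), 1/(m^2 s)."""
    neq = equilibrium_density(Vm, params)
    out = params.alpha * np.exp(_vsq(Vm, params.V_ep)) * (1.0 - np.asarray(N) / neq)
    return out if np.ndim(out) else float(out)


def effective_tension(A_p: float, A_cell: float, params: PoreModelParams) -> float:
    """Whole-cell effective membrane tension (N/m), decreasing in pore area."""
    if not 0.0 <= A_p < A_cell:
        raise ValueError(f"pore area A_p={A_p:.3e} outside [0, A_cell={A_cell:.3e})")
    x = A_p / A_cell
    return 2.0 * params.sigma_prime - (2.0 * params.sigma_prime - params.sigma_0) / (1.0 - x) ** 2


def radius_rate(r, Vm, sigma_eff: float, params: PoreModelParams, k_B: float, T: float):
    """dr/dt (m/s) for a pore of radius r at membrane potential Vm.

    Overdamped dynamics: mobility D_p/(k_B T) times the net force —
    electric (prop. Vm^2), steric repulsion (prop. (r*/r)^4 / r), edge
    contraction (-2 pi gamma) and tension expansion (+2 pi sigma_eff r).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < params.r_star * (1.0 - 1e-12)):
        raise ValueError("pore radius below the minimum radius r_star")
    vm2 = np.asarray(Vm, dtype=float) ** 2
    force = (
        vm2 * params.F_max / (1.0 + params.r_h / (r_arr + params.r_t))
        + 4.0 * params.beta * (params.r_star / r_arr) ** 4 / r_arr
        - 2.0 * np.pi * params.gamma
        + 2.0 * np.pi * sigma_eff * r_arr
    )
    out = params.D_p / (k_B * T) * force
    return out if np.ndim(out) else float(out)


@dataclass
class PoreState:
    """Per-angle pore densities and radius cohorts.

    ``radii``/``counts`` are (N_theta, MAX_COHORTS) arrays; ``n_slots[k]``
    slots are in use at angle k and the last used slot is the nursery that
    collects newly created pores.  ``N`` (1/m^2) times the element area
    equals the summed cohort count at each angle exactly, by construction.
    """

    N: np.ndarray
    radii: np.ndarray
    counts: np.ndarray
    n_slots: np.ndarray
    A_theta: np.ndarray
    A_cell: float
    steps: int = 0

    @staticmethod
    def initial(A_theta: np.ndarray, params: PoreModelParams,
                k_B: float, T: float) -> "PoreState":
        """Resting state: density N0 everywhere, one cohort at the
        zero-voltage equilibrium radius per angle (a fraction of a pore on a
        cell this small, but bookkeeping-exact) plus an empty nursery."""
        A_theta = np.asarray(A_theta, dtype=float)
        nt = len(A_theta)
        r0 = equilibrium_radius(params, k_B, T)
        radii = np.full((nt, MAX_COHORTS), params.r_star)
        counts = np.zeros((nt, MAX_COHORTS))
        radii[:, 0] = r0
        counts[:, 0] = params.N0 * A_theta
        n_slots = np.full(nt, 2, dtype=int)  # slot 1 is the nursery
        return PoreState(np.full(nt, params.N0), radii, counts, n_slots,
                         A_theta, float(np.sum(A_theta)))

    def pore_area(self) -> float:
        """Total open pore area over the whole cell, m^2."""
        return float(np.sum(self.counts * np.pi * self.radii**2))

    def area_per_theta(self) -> np.ndarray:
        return np.sum(self.counts * np.pi * self.radii**2, axis=1)

    def fractional_area(self) -> np.ndarray:
        """Open-area fraction f_p per theta element."""
        return self.area_per_theta() / self.A_theta

    def mean_radius(self) -> np.ndarray:
        tot = np.sum(self.counts, axis=1)
        num = np.sum(self.counts * self.radii, axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, num / np.maximum(tot, 1e-300), np.nan)

    def cohort_count(self) -> np.ndarray:
        """Number of non-empty cohorts per angle (diagnostic)."""
        return np.sum(self.counts > 0, axis=1)


def equilibrium_radius(params: PoreModelParams, k_B: float, T: float,
                       sigma_eff: float | None = None) -> float:
    """Radius r_eq > r_star where dr/dt = 0 at Vm = 0 (bracketed root)."""
    from scipy.optimize import brentq

    s = params.sigma_0 if sigma_eff is None else sigma_eff

    def f(r):
        return radius_rate(r, 0.0, s, params, k_B, T)

    lo = params.r_star
    hi = params.r_star * 2.0
    # the force is steric-dominated (positive) at r* and edge-dominated
    # (negative) beyond the energy minimum, so expand until the sign flips
    while f(hi) > 0 and hi < 1e-6:
        hi *= 2.0
    if f(lo) <= 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-15))


def _merge_nearest(radii: np.ndarray, counts: np.ndarray, n: int) -> int:
    """In-place nearest-radius pair merge among slots [0, n); returns n-1."""
    order = np.argsort(radii[:n])
    rs, cs = radii[order], counts[order]
    gaps = np.diff(rs)
    i = int(np.argmin(gaps))
    c = cs[i] + cs[i + 1]
    r = np.sqrt((cs[i] * rs[i] ** 2 + cs[i + 1] * rs[i + 1] ** 2) / c) if c > 0 else rs[i]
    merged_r = np.concatenate([rs[:i], [r], rs[i + 2:]])
    merged_c = np.concatenate([cs[:i], [c], cs[i + 2:]])
    radii[: n - 1] = merged_r
    counts[: n - 1] = merged_c
    radii[n - 1] = merged_r.min()  # empty slot; keep the radius admissible
    counts[n - 1] = 0.0
    return n - 1


def step_pores(
    state: PoreState,
    Vm: np.ndarray,
    dt: float,
    params: PoreModelParams,
    constants: PhysicalConstants,
    T: float,
) -> PoreState:
    """Advance pore densities and cohort radii by one explicit step.

    Sub-steps the density ODE internally whenever its change would exceed
    10% of the local equilibrium density in a single step.  Radii use the
    whole-cell effective tension evaluated at the current pore area.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    A_p = state.pore_area()
    if A_p >= state.A_cell:
        raise RuntimeError("total pore area reached the whole cell area; "
                           "the tension model is outside its validity range")
    sigma_eff = effective_tension(A_p, state.A_cell, params)

    Vm = np.asarray(Vm, dtype=float)
    neq = equilibrium_density(Vm, params)
    rate0 = density_rate(state.N, Vm, params)
    nsub = int(np.ceil(np.max(np.abs(rate0) * dt / (0.1 * neq))))
    nsub = max(1, min(nsub, 1000))
    h = dt / nsub

    N = state.N.copy()
    radii = state.radii.copy()
    counts = state.counts.copy()
    n_slots = state.n_slots.copy()
    nt = len(N)
    nursery = n_slots - 1

    for _ in range(nsub):
        dN = density_rate(N, Vm, params) * h
        grow = dN > 0
        if np.any(grow):
            # merge the newborn pores (radius r_star) into the nursery cohort
            add = np.where(grow, dN * state.A_theta, 0.0)
            idx = (np.arange(nt), nursery)
            c_old = counts[idx]
            r_old = radii[idx]
            c_new = c_old + add
            with np.errstate(invalid="ignore", divide="ignore"):
                r_new = np.sqrt(
                    (c_old * r_old**2 + add * params.r_star**2)
                    / np.where(c_new > 0, c_new, 1.0)
                )
            radii[idx] = np.where(c_new > 0, r_new, params.r_star)
            counts[idx] = c_new
        shrink = (dN < 0) & (N > 0)
        if np.any(shrink):
            scale = np.where(shrink, np.maximum(0.0, 1.0 + dN / np.where(N > 0, N, 1.0)), 1.0)
            counts *= scale[:, None]
        N = np.maximum(N + dN, 0.0)

    # radius dynamics with the tension frozen over dt (first-order splitting)
    dr = radius_rate(radii, Vm[:, None], sigma_eff, params, constants.k_B, T)
    radii = np.maximum(radii + dr * dt, params.r_star)

    steps = state.steps + 1
    if steps % PROMOTE_EVERY == 0:
        # open a fresh nursery slot; merge nearest cohorts when out of slots
        for k in range(nt):
            if n_slots[k] >= MAX_COHORTS:
                n_slots[k] = _merge_nearest(radii[k], counts[k], n_slots[k])
            radii[k, n_slots[k]] = params.r_star
            counts[k, n_slots[k]] = 0.0
            n_slots[k] += 1

    new = PoreState(N, radii, counts, n_slots, state.A_theta, state.A_cell, steps)
    if new.pore_area() >= new.A_cell:
        raise RuntimeError("pore area exceeded the cell area after the step")
    return new
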