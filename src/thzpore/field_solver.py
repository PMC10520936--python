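"""Quasi-static electric potential and membrane-potential update.

The potential obeys Laplace's equation in the intracellular and extracellular
ohmic media (bulk net charge ~ 0), with

* a potential jump Phi_i - Phi_o = Vm(theta) across the membrane,
* continuity of normal conduction current through the membrane,
* the applied-field Dirichlet condition Phi = -E(t) r cos(theta) on the
  outer boundary, and
* axisymmetry (no phi dependence), with reflection at the poles.

The discretization is 2-D (r, theta) finite differences on uniform grids in
each medium, sharing a single centre node at r = 0 and L'Hopital-regularized
stencils on the polar axis.  Because the operator is linear and the geometry
fixed, the solution is an affine function of (E, Vm); the solver precomputes
the normal-current response J_n = j_E * E + M @ Vm once (one sparse
factorization plus N_theta + 1 solves) and the time loop reuses it.

The membrane potential then advances by current continuity:

    C_m dVm/dt = J_n - g1 (Vm - V_rest) - I_p

per polar angle, where I_p is the pore current density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .parameters import CellGeometry, MembraneElectrical


@dataclass
class PotentialField:
    """Solved potentials on the interior/exterior (r, theta) grids."""

    r_in: np.ndarray  # (N_r_in,) radii incl. centre and membrane face
    r_out: np.ndarray  # (N_r_out,) radii incl. membrane face and boundary
    theta: np.ndarray  # (N_theta,)
    Phi_in: np.ndarray  # (N_r_in, N_theta)
    Phi_out: np.ndarray  # (N_r_out, N_theta)
    J_n: np.ndarray  # (N_theta,) normal conduction current density, A/m^2


class LaplaceSolver:
    """Factorized axisymmetric Laplace solver for one geometry."""

    def __init__(self, geometry: CellGeometry, electrical: MembraneElectrical):
        self.geometry = geometry
        self.electrical = electrical
        self.theta = geometry.theta_nodes()
        nt = geometry.N_theta
        ni = geometry.N_r_in  # nodes at r = 0..R_cell; index 0 is the centre
        no = geometry.N_r_out
        self.r_in = np.linspace(0.0, geometry.R_cell, ni)
        self.r_out = np.linspace(geometry.R_cell, geometry.R_domain, no)
        self.dr_in = self.r_in[1] - self.r_in[0]
        self.dr_out = self.r_out[1] - self.r_out[0]
        self.dth = self.theta[1] - self.theta[0]

        # unknown layout: [centre] + interior (i=1..ni-1, all theta) + exterior
        self.n_in = (ni - 1) * nt
        self.n_out = no * nt
        self.n = 1 + self.n_in + self.n_out
        self._build_matrix()
        self._build_responses()

    # ---- index helpers -------------------------------------------------
    def _ii(self, i: int, k: int) -> int:
        """interior node i (1-based radial), theta k."""
        return 1 + (i - 1) * self.geometry.N_theta + k

    def _io(self, j: int, k: int) -> int:
        """exterior node j (0 = membrane face), theta k."""
        return 1 + self.n_in + j * self.geometry.N_theta + k

    # ---- assembly ------------------------------------------------------
    def _laplace_row(self, add, idx, r, dr, theta_k, k, nt, neighbor):
        """5-point axisymmetric spherical Laplacian at a bulk node."""
        dth = self.dth
        # radial part: (1/r^2) d/dr (r^2 dPhi/dr)
        rp = r + 0.5 * dr
        rm = r - 0.5 * dr
        cr_p = rp**2 / (r**2 * dr**2)
        cr_m = rm**2 / (r**2 * dr**2)
        add(idx, neighbor(+1, 0), cr_p)
        add(idx, neighbor(-1, 0), cr_m)
        diag = -(cr_p + cr_m)
        # angular part
        th = theta_k
        if k == 0 or k == nt - 1:
            # pole: (1/(r^2 sin) d/dth(sin dPhi/dth)) -> (2/r^2) d2Phi/dth2,
            # with reflection Phi(-dth) = Phi(+dth)
            c = 4.0 / (r**2 * dth**2)
            add(idx, neighbor(0, +1 if k == 0 else -1), c)
            diag -= c
        else:
            sp_ = np.sin(th + 0.5 * dth)
            sm_ = np.sin(th - 0.5 * dth)
            ct_p = sp_ / (r**2 * np.sin(th) * dth**2)
            ct_m = sm_ / (r**2 * np.sin(th) * dth**2)
            add(idx, neighbor(0, +1), ct_p)
            add(idx, neighbor(0, -1), ct_m)
            diag -= ct_p + ct_m
        add(idx, idx, diag)

    def _build_matrix(self) -> None:
        g = self.geometry
        nt, ni, no = g.N_theta, g.N_r_in, g.N_r_out
        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        # solid-angle weights of the theta elements (used for the centre node)
        edges = np.concatenate([[0.0], 0.5 * (self.theta[1:] + self.theta[:-1]),
                                [np.pi]])
        self.w_theta = np.cos(edges[:-1]) - np.cos(edges[1:])

        # centre node: Phi_c = solid-angle mean of Phi(r_1, theta)
        add(0, 0, -1.0)
        wsum = self.w_theta.sum()
        for k in range(nt):
            add(0, self._ii(1, k), self.w_theta[k] / wsum)

        # interior bulk nodes i = 1..ni-2
        for i in range(1, ni - 1):
            r = self.r_in[i]
            for k in range(nt):
                idx = self._ii(i, k)

                def nb(dirr, dirt, i=i, k=k):
                    i2, k2 = i + dirr, k + dirt
                    if i2 == 0:
                        return 0  # centre
                    return self._ii(i2, k2)

                self._laplace_row(add, idx, r, self.dr_in, self.theta[k], k, nt, nb)

        # interior membrane-face node (i = ni-1): current continuity
        # sigma_i dPhi_i/dr = sigma_o dPhi_o/dr with second-order one-sided
        # differences on both sides
        si, so = self.electrical.sigma_i, self.electrical.sigma_o
        for k in range(nt):
            idx = self._ii(ni - 1, k)
            ci = si / (2.0 * self.dr_in)
            co = so / (2.0 * self.dr_out)
            add(idx, self._ii(ni - 1, k), 3.0 * ci)
            add(idx, self._ii(ni - 2, k), -4.0 * ci)
            add(idx, self._ii(ni - 3, k) if ni >= 4 else 0, 1.0 * ci)
            add(idx, self._io(0, k), 3.0 * co)
            add(idx, self._io(1, k), -4.0 * co)
            add(idx, self._io(2, k), 1.0 * co)
            # note signs: outward derivative from inside uses (3 f0 -4 f-1 + f-2)/(2dr),
            # from outside (-3 f0 + 4 f1 - f2)/(2dr); equation written as
            # si*dPhi_i/dr - so*dPhi_o/dr = 0

        # exterior membrane-face node (j = 0): potential jump Phi_i - Phi_o = Vm
        for k in range(nt):
            idx = self._io(0, k)
            add(idx, self._ii(ni - 1, k), 1.0)
            add(idx, self._io(0, k), -1.0)
            # rhs: Vm_k (set in solve)

        # exterior bulk nodes j = 1..no-2
        for j in range(1, no - 1):
            r = self.r_out[j]
            for k in range(nt):
                idx = self._io(j, k)

                def nb(dirr, dirt, j=j, k=k):
                    return self._io(j + dirr, k + dirt)

                self._laplace_row(add, idx, r, self.dr_out, self.theta[k], k, nt, nb)

        # outer boundary: Dirichlet Phi = -E r cos(theta)
        for k in range(nt):
            idx = self._io(no - 1, k)
            add(idx, idx, 1.0)
            # rhs: -E R_domain cos(theta_k)

        A = sp.csc_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )
        # equilibrate rows: the Laplacian rows scale like 1/dr^2 (~1e13)
        # while the jump rows are O(1); row scaling keeps the LU well posed
        scale = 1.0 / np.abs(A).max(axis=1).toarray().ravel()
        self._row_scale = scale
        self.A = sp.diags(scale) @ A
        self._lu = splu(sp.csc_matrix(self.A))

    def _rhs(self, E: float, Vm: np.ndarray) -> np.ndarray:
        g = self.geometry
        b = np.zeros(self.n)
        for k in range(g.N_theta):
            b[self._io(0, k)] = Vm[k]  # jump condition row: Phi_i - Phi_o = Vm
            b[self._io(g.N_r_out - 1, k)] = -E * g.R_domain * np.cos(self.theta[k])
        return b * self._row_scale

    def _unpack(self, x: np.ndarray):
        g = self.geometry
        nt, ni, no = g.N_theta, g.N_r_in, g.N_r_out
        Phi_in = np.empty((ni, nt))
        Phi_in[0, :] = x[0]
        Phi_in[1:, :] = x[1 : 1 + self.n_in].reshape(ni - 1, nt)
        Phi_out = x[1 + self.n_in :].reshape(no, nt)
        return Phi_in, Phi_out

    def _jn(self, Phi_in: np.ndarray) -> np.ndarray:
        """Normal conduction current density into the membrane from inside,
        J_n = -sigma_i dPhi_i/dr at r = R_cell (second-order one-sided)."""
        si = self.electrical.sigma_i
        return -si * (3.0 * Phi_in[-1] - 4.0 * Phi_in[-2] + Phi_in[-3]) / (2.0 * self.dr_in)

    def _build_responses(self) -> None:
        """J_n as an affine function of (E, Vm): J_n = j_E * E + M @ Vm."""
        nt = self.geometry.N_theta
        x = self._lu.solve(self._rhs(1.0, np.zeros(nt)))
        Phi_in, _ = self._unpack(x)
        self.j_E = self._jn(Phi_in)
        M = np.empty((nt, nt))
        for k in range(nt):
            vm = np.zeros(nt)
            vm[k] = 1.0
            x = self._lu.solve(self._rhs(0.0, vm))
            Phi_in, _ = self._unpack(x)
            M[:, k] = self._jn(Phi_in)
        self.M = M

    # ---- public API ----------------------------------------------------
    def normal_current(self, E: float, Vm: np.ndarray) -> np.ndarray:
        """J_n(theta) via the precomputed affine response (A/m^2)."""
        return self.j_E * E + self.M @ Vm

    def solve(self, E: float, Vm: np.ndarray) -> PotentialField:
        """Full potential solve (for diagnostics and field output)."""
        Vm = np.asarray(Vm, dtype=float)
        if Vm.shape != (self.geometry.N_theta,):
            raise ValueError("Vm must be defined on every theta node")
        if not np.isfinite(E) or not np.all(np.isfinite(Vm)):
            raise ValueError("E and Vm must be finite")
        x = self._lu.solve(self._rhs(E, Vm))
        if not np.all(np.isfinite(x)):
            raise RuntimeError("Laplace solve produced non-finite potentials")
        Phi_in, Phi_out = self._unpack(x)
        return PotentialField(self.r_in, self.r_out, self.theta,
                              Phi_in, Phi_out, self._jn(Phi_in))


def solve_potential(geometry: CellGeometry, electrical: MembraneElectrical,
                    Vm, E_applied: float) -> PotentialField:
    """One-off potential solve (builds and discards the factorization)."""
    return LaplaceSolver(geometry, electrical).solve(E_applied, np.asarray(Vm, float))


def explicit_dt_bound(solver: LaplaceSolver) -> float:
    """Largest stable explicit step for the membrane ODE coupled to the
    bulk response: dt < 2 C_m / |lambda_max(M)| (g1 and pore conductance
    only tighten this marginally at physiological values)."""
    lam = np.linalg.eigvals(solver.M)
    lam_max = np.max(np.abs(np.real(lam)))
    return 2.0 * solver.electrical.C_m / lam_max


def step_membrane_potential(
    Vm: np.ndarray,
    J_n: np.ndarray,
    I_p_density: np.ndarray,
    electrical: MembraneElectrical,
    dt: float,
    dt_bound: float | None = None,
) -> np.ndarray:
    """Advance C_m dVm/dt = J_n - g1 (Vm - V_rest) - I_p by explicit Euler."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt_bound is not None and dt > dt_bound:
        raise ValueError(
            f"dt = {dt:.3e} s exceeds the explicit stability bound "
            f"{dt_bound:.3e} s; reduce the step"
        )
    if not (np.all(np.isfinite(J_n)) and np.all(np.isfinite(I_p_density))):
        raise ValueError("current densities must be finite")
    dv = (J_n - electrical.g1 * (Vm - electrical.V_rest) - I_p_density) / electrical.C_m
    return Vm + dt * dv


def membrane_conductivity(I_p_density, Vm, fp=None, sigma_pore: float = 0.0,
                          d_mem: float = 5e-9, v_floor: float = 1e-3):
    """Diagnostic per-theta membrane conductivity, S/m^2.

    I_p/Vm where |Vm| exceeds a floor voltage; otherwise the pore-geometry
    estimate f_p * sigma_pore / d_mem; identically zero with no open pores.
    """
    I_p = np.asarray(I_p_density, dtype=float)
    Vm_ = np.asarray(Vm, dtype=float)
    geom = np.zeros_like(I_p) if fp is None else np.asarray(fp) * sigma_pore / d_mem
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(Vm_) > v_floor, I_p / np.where(Vm_ == 0, 1, Vm_), geom)
    out = np.where((I_p == 0) & ((fp is None) | (geom == 0)), 0.0, ratio)
    return out if np.ndim(out) else float(out)
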