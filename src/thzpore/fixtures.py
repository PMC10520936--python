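"""Synthetic inputs and independent oracles.

Everything needed to exercise the pipeline without external data lives here:

* seeded synthetic whole-cell I-V datasets with known ground-truth pump
  parameters (stand-ins for voltage-clamp measurements, for testing the
  fitting stage by parameter recovery);
* the classical spherical-cell induced-voltage closed form (the Schwan
  equation with RC charging), an analytic reference for the field solver;
* a linear-algebra steady-state oracle for the 4-state pump cycle,
  independent of the closed-form cycle-rate expression;
* miniature run configurations that complete in seconds.

These live in the package (not the test tree) so an installation can be
re-verified anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .atpase import CycleRates, iv_curve
from .parameters import AtpaseParams, ParameterBundle, default_bundle


@dataclass
class SyntheticIvDataset:
    """Synthetic voltage-clamp pump I-V points with known truth."""

    Vm: np.ndarray  # V
    I: np.ndarray  # A
    sigma: np.ndarray  # A, per-point uncertainty
    true_params: AtpaseParams
    seed: int

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.Vm, self.I, self.sigma])


def make_iv_dataset(
    true_params: AtpaseParams,
    Vm_grid,
    noise_fraction: float = 0.05,
    seed: int = 0,
    concentrations: dict[str, float] | None = None,
    T: float = 310.0,
) -> SyntheticIvDataset:
    """I-V points from the cycle model plus seeded Gaussian noise.

    The noise standard deviation is ``noise_fraction`` of the maximum |I|
    on the grid (the per-point sigma column reports it).
    """
    if noise_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    vm = np.asarray(Vm_grid, dtype=float)
    conc = concentrations or {}
    ideal = iv_curve(true_params, vm, T=T, **conc)
    scale = noise_fraction * np.max(np.abs(ideal))
    rng = np.random.default_rng(seed)
    noisy = ideal + (rng.normal(size=vm.shape) * scale if scale > 0 else 0.0)
    sigma = np.full_like(vm, scale if scale > 0 else 1.0)
    return SyntheticIvDataset(vm, noisy, sigma, true_params, seed)


def schwan_reference(E0, R_cell, sigma_i, sigma_o, C_m, g1, t, theta):
    """Induced membrane voltage of a spherical cell in a uniform step field.

    First-order closed form: Vm_ind = 1.5 E0 R cos(theta) (1 - exp(-t/tau))
    with the charging time constant

        tau = R C_m (1/sigma_i + 1/(2 sigma_o)) / (1 + R g1 (1/sigma_i + 1/(2 sigma_o)))

    For g1 = 0 this is the classical membrane charging constant; the g1 term
    is the standard leak correction (it also scales the plateau by the same
    factor).  Derivation sketch: the series access resistance per unit area
    of a spherical cell is R(1/sigma_i + 1/(2 sigma_o))/1.5; charging it
    through C_m in parallel with g1 gives the RC form above.
    """
    rho = 1.0 / sigma_i + 1.0 / (2.0 * sigma_o)
    denom = 1.0 + R_cell * g1 * rho
    tau = R_cell * C_m * rho / denom
    amp = 1.5 * E0 * R_cell / denom
    t = np.asarray(t, dtype=float)
    out = amp * np.cos(theta) * (1.0 - np.exp(-t / tau))
    return out if np.ndim(out) else float(out)


def schwan_time_constant(R_cell, sigma_i, sigma_o, C_m, g1=0.0) -> float:
    rho = 1.0 / sigma_i + 1.0 / (2.0 * sigma_o)
    return R_cell * C_m * rho / (1.0 + R_cell * g1 * rho)


def cycle_steady_state_oracle(rates: CycleRates) -> float:
    """Net cycle flux of the 4-state chain by solving the stationary
    distribution (independent check of the closed-form cycle rate).

    States 1..4; forward transitions i -> i+1 at rate Ri+, backward
    i+1 -> i at rate Ri- (indices mod 4).  Returns the net stationary flux
    across the 1 -> 2 transition for a single enzyme.

    The 4x4 stationary system is solved by Gaussian elimination in exact
    rational arithmetic (binary floats convert to rationals exactly), so
    the oracle's only error is the final conversion back to float.  Rate
    vectors spanning many decades would otherwise lose ~10 digits to
    conditioning in a floating-point solve.
    """
    from fractions import Fraction

    vals = [np.asarray(v, dtype=float) for v in rates.as_tuple()]
    if any(v.ndim > 0 for v in vals):
        raise ValueError("oracle takes scalar rates; vectorize externally")
    r = [float(v) for v in vals]
    fwd = [Fraction(x) for x in r[:4]]
    bwd = [Fraction(x) for x in r[4:]]  # bwd[i]: state i+1 -> state i
    Q = [[Fraction(0)] * 4 for _ in range(4)]
    for i in range(4):
        j = (i + 1) % 4
        Q[j][i] += fwd[i]  # i -> j
        Q[i][i] -= fwd[i]
        Q[i][j] += bwd[i]  # j -> i
        Q[j][j] -= bwd[i]
    # replace the last balance row (redundant) with the normalization sum = 1
    A = [row[:] for row in Q[:3]] + [[Fraction(1)] * 4]
    b = [Fraction(0)] * 3 + [Fraction(1)]
    for col in range(4):
        piv = next((k for k in range(col, 4) if A[k][col] != 0), None)
        if piv is None:
            raise ValueError("chain is reducible: singular stationary system")
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        for k in range(4):
            if k != col and A[k][col] != 0:
                f = A[k][col] / A[col][col]
                for c in range(col, 4):
                    A[k][c] -= f * A[col][c]
                b[k] -= f * b[col]
    pi = [b[k] / A[k][k] for k in range(4)]
    if any(p < 0 for p in pi):
        raise ValueError("chain appears reducible: negative stationary mass")
    return float(pi[0] * fwd[0] - pi[1] * bwd[0])


def mini_config(scale: float = 0.25) -> ParameterBundle:
    """A coarse-grid configuration whose full run completes in seconds.

    ``scale`` in (0, 1] shrinks the radial grids (theta keeps the seven
    reportable angles); scale 1 returns the full default configuration.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    b = default_bundle("rat_neostriatal")
    if scale == 1.0:
        return b
    g = b.geometry
    geometry = dataclasses.replace(
        g,
        N_theta=7,
        N_r_in=max(6, int(round(g.N_r_in * scale))),
        N_r_out=max(6, int(round(g.N_r_out * scale))),
    )
    return dataclasses.replace(b, geometry=geometry)
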