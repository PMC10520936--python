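"""4-state Na+,K+-ATPase cycle model.

The pump is a four-state kinetic cycle with voltage-dependent ion binding.
Eight composite forward/backward rates R1+..R4- combine the rate constants,
saturating binding fractions (cubic in Na, quadratic in K), MgATP/MgADP/
phosphate ligand terms and exponential voltage partitions.  The steady-state
cycle rate v_cyc is the closed-form King-Altman expression (forward product
minus backward product over the 16-term spanning-tree sum); whole-cell pump
current is I = F_c * v_cyc, and the 3 Na+ : 2 K+ stoichiometry fixes the
molar flows.  Positive current means positive charge leaving the cell.

Power accounting: one ATP is hydrolyzed per cycle (one third of the Na+
transport rate).  ``power`` offers two modes: ``per_molecule`` multiplies the
ATP consumption rate in molecules/s (I/q_ele) by the per-molecule hydrolysis
energy Q_ATP = 10 k_B T; ``literal`` additionally divides by N_A, i.e. it
treats I/q_ele/N_A (mol/s) as the consumption rate while keeping Q_ATP per
molecule.  The per-molecule mode is the dimensionally consistent one and is
the reporting default; their ratio is exactly N_A.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import PhysicalConstants
from .parameters import AtpaseParams

#: |argument| clamp for the voltage exponentials.  With partition
#: coefficients |d| <= 0.7 the clamp engages only beyond |Vm| ~ 1.9 V,
#: far outside the physiological range and above the largest excursions
#: that leave the pump model meaningful.
EXP_CLAMP = 50.0

# raised when any voltage exponential is clamped (diagnostic, not an error)
_clamp_warned = False


@dataclass
class CycleRates:
    """Composite forward (p) / backward (m) rates of the 4-state cycle."""

    R1p: np.ndarray
    R2p: np.ndarray
    R3p: np.ndarray
    R4p: np.ndarray
    R1m: np.ndarray
    R2m: np.ndarray
    R3m: np.ndarray
    R4m: np.ndarray

    def as_tuple(self):
        return (self.R1p, self.R2p, self.R3p, self.R4p,
                self.R1m, self.R2m, self.R3m, self.R4m)


def _vexp(arg):
    """exp with a documented clamp against overflow at extreme voltages."""
    global _clamp_warned
    a = np.asarray(arg, dtype=float)
    if np.any(np.abs(a) > EXP_CLAMP) and not _clamp_warned:
        warnings.warn(
            f"voltage exponential argument clamped at +/-{EXP_CLAMP}; "
            "membrane potential far outside the model's validity range",
            RuntimeWarning,
            stacklevel=3,
        )
        _clamp_warned = True
    return np.exp(np.clip(a, -EXP_CLAMP, EXP_CLAMP))


def cycle_rates(
    Vm,
    c_Na_i,
    c_Na_o,
    c_K_i,
    c_K_o,
    params: AtpaseParams,
    T: float = 310.0,
    constants: PhysicalConstants | None = None,
) -> CycleRates:
    """Evaluate the eight composite rates at membrane potential Vm.

    All arguments broadcast; concentrations in mol/m^3, Vm in volts.
    """
    c = constants if constants is not None else PhysicalConstants.at_temperature(T)
    fv = c.F * np.asarray(Vm, dtype=float) / (c.R_u * T)

    x_nai = (np.asarray(c_Na_i) / params.kd_Nai0) * _vexp(-params.d_Nai * fv)
    x_ki = (np.asarray(c_K_i) / params.kd_Ki0) * _vexp(-params.d_Ki * fv)
    x_nao = (np.asarray(c_Na_o) / params.kd_Nao0) * _vexp(-params.d_Nao * fv)
    x_ko = (np.asarray(c_K_o) / params.kd_Ko0) * _vexp(-params.d_Ko * fv)

    den_i = (1.0 + x_nai) ** 3 + (1.0 + x_ki) ** 2 - 1.0
    den_o = (1.0 + x_nao) ** 3 + (1.0 + x_ko) ** 2 - 1.0

    y = params.c_MgATP / params.kd_MgATP

    R1p = params.k1p * x_nai**3 / den_i
    R2p = params.k2p * np.ones_like(den_i)
    R3p = params.k3p * x_ko**2 / den_o
    R4p = params.k4p * y / (1.0 + y) * np.ones_like(den_i)
    R1m = params.k1m * params.c_MgADP * np.ones_like(den_i)
    R2m = params.k2m * x_nao**3 / den_o
    R3m = params.k3m * params.c_P * 10.0 ** (3.0 - params.pH) / (1.0 + y) \
        * np.ones_like(den_i)
    R4m = params.k4m * x_ki**2 / den_i
    return CycleRates(R1p, R2p, R3p, R4p, R1m, R2m, R3m, R4m)


def cycle_rate(rates: CycleRates):
    """Steady-state cycle rate v_cyc (1/s), closed King-Altman form.

    (forward product - backward product) over the 16 spanning-tree terms.
    """
    R1p, R2p, R3p, R4p, R1m, R2m, R3m, R4m = rates.as_tuple()
    num = R1p * R2p * R3p * R4p - R1m * R2m * R3m * R4m
    den = (
        R1m * R2m * R3m + R1p * R2m * R3m + R1p * R2p * R3m + R1p * R2p * R3p
        + R2m * R3m * R4m + R2p * R3m * R4m + R2p * R3p * R4m + R2p * R3p * R4p
        + R1m * R3m * R4m + R1m * R3p * R4m + R1m * R3p * R4p + R1p * R3p * R4p
        + R1m * R2m * R4m + R1m * R2m * R4p + R1p * R2m * R4p + R1p * R2p * R4p
    )
    den = np.asarray(den, dtype=float)
    if np.any(den == 0.0):
        raise ZeroDivisionError("degenerate cycle parameterization: zero denominator")
    out = num / den
    return out if np.ndim(out) else float(out)


def pump_current(v_cyc, F_c: float):
    """Whole-cell pump current I = F_c * v_cyc (A)."""
    out = F_c * np.asarray(v_cyc, dtype=float)
    return out if np.ndim(out) else float(out)


def pump_flows(I, constants: PhysicalConstants):
    """Whole-cell molar flows (J_Na, J_K) in mol/s: 3 out, 2 in per cycle."""
    base = np.asarray(I, dtype=float) / constants.q_ele / constants.N_A
    return 3.0 * base, -2.0 * base


def pump_flows_theta(I, A_theta, A_cell: float, constants: PhysicalConstants):
    """Per-angular-element molar flows, proportional to element area.

    Summing over elements recovers the whole-cell flows exactly when
    sum(A_theta) == A_cell.
    """
    frac = np.asarray(A_theta, dtype=float) / A_cell
    j_na, j_k = pump_flows(I, constants)
    return j_na * frac, j_k * frac


def power(I, constants: PhysicalConstants, mode: str = "per_molecule"):
    """ATP power dissipation P (W) for pump current I (A).

    per_molecule: P = Q_ATP * I / q_ele           (Q_ATP per molecule)
    literal:      P = Q_ATP * I / q_ele / N_A     (printed form)
    """
    base = constants.Q_ATP * np.asarray(I, dtype=float) / constants.q_ele
    if mode == "per_molecule":
        out = base
    elif mode == "literal":
        out = base / constants.N_A
    else:
        raise ValueError(f"unknown power mode {mode!r}")
    return out if np.ndim(out) else float(out)


def iv_curve(
    params: AtpaseParams,
    Vm_grid,
    c_Na_i: float = 12.0,
    c_Na_o: float = 145.0,
    c_K_i: float = 139.0,
    c_K_o: float = 4.0,
    T: float = 310.0,
):
    """Whole-cell pump current I(Vm) at fixed concentrations (A)."""
    rates = cycle_rates(Vm_grid, c_Na_i, c_Na_o, c_K_i, c_K_o, params, T=T)
    return pump_current(cycle_rate(rates), params.F_c)


_LOG_SCALE_FIELDS = {
    "k1p", "k2p", "k3p", "k4p", "k1m", "k2m", "k3m", "k4m",
    "kd_Nai0", "kd_Nao0", "kd_Ki0", "kd_Ko0", "kd_MgATP", "F_c",
}


@dataclass
class FitResult:
    params: AtpaseParams
    free: list[str]
    estimates: dict[str, float]
    std_errors: dict[str, float]  # linear-scale (delta method for log params)
    std_errors_internal: dict[str, float]  # log-scale for positive params
    residuals: np.ndarray
    cost: float
    condition_number: float
    identifiability_warning: bool
    n_starts: int

    def within_n_se(self, name: str, value: float, n: float = 3.0) -> bool:
        """Is ``value`` within n standard errors of the estimate, measured
        on the parameter's natural scale (log for positive parameters)?"""
        est = self.estimates[name]
        se = self.std_errors_internal[name]
        if se == 0:
            return value == est
        if name in _LOG_SCALE_FIELDS:
            return abs(np.log(value / est)) <= n * se
        return abs(value - est) <= n * se


def fit_iv(
    data,
    free: list[str],
    initial: AtpaseParams,
    seed: int = 0,
    concentrations: dict[str, float] | None = None,
    T: float = 310.0,
    n_starts: int = 4,
    max_nfev: int = 2000,
    bound_decades: float = 1.0,
    se_method: str = "profile",
) -> FitResult:
    """Weighted least-squares fit of the cycle-model I-V to data points.

    Parameters
    ----------
    data : array-like shape (n, 2) or (n, 3)
        Columns Vm (V), I (A) and optionally sigma_I (A).  Uniform unit
        weights are used when no uncertainties are supplied.
    free : list of AtpaseParams field names to fit (empty -> residuals only).
    initial : starting parameter set (also supplies the fixed values).
    seed : seeds the multi-start perturbations (the cycle model is
        parameter-degenerate; multi-start mitigates local minima).
    bound_decades : half-width of the search box around the initial guess
        for positive parameters, in decades.  The cycle model has an exact
        F_c/kd scaling ridge once a binding step unsaturates, so unbounded
        fits of noisy data can run away along it; dissociation constants
        and the current scale are physiologically known to order of
        magnitude, which the default box encodes.

    Positive-definite parameters are fitted in log space.  Standard errors
    default to profile-likelihood intervals (``se_method="profile"``): each
    free parameter is stepped away from its estimate with the others refit,
    and the 1-sigma point is where the profiled cost rises by s^2/2; the
    model's curved flat valleys make the local Gauss-Newton covariance
    (``se_method="gauss-newton"``) overconfident along them.  A
    near-singular Hessian triggers a practical-identifiability warning.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("data must have columns Vm, I[, sigma_I]")
    vm, iobs = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] == 3 else np.ones_like(iobs)
    if np.any(sigma <= 0):
        raise ValueError("uncertainties must be positive")
    conc = {"c_Na_i": 12.0, "c_Na_o": 145.0, "c_K_i": 139.0, "c_K_o": 4.0}
    if concentrations:
        conc.update(concentrations)

    valid = {f.name for f in dataclasses.fields(AtpaseParams)}
    for name in free:
        if name not in valid:
            raise ValueError(f"unknown parameter {name!r}")
    if len(vm) < max(len(free), 1):
        raise ValueError("need at least as many points as free parameters")

    def pack(p: AtpaseParams) -> np.ndarray:
        vals = []
        for name in free:
            v = getattr(p, name)
            vals.append(np.log(v) if name in _LOG_SCALE_FIELDS else v)
        return np.array(vals)

    def unpack(x: np.ndarray) -> AtpaseParams:
        p = dataclasses.replace(initial)
        for name, xv in zip(free, x):
            setattr(p, name, float(np.exp(xv)) if name in _LOG_SCALE_FIELDS else float(xv))
        return p

    # bring the weighted residuals to O(1): pump currents are ~1e-12 A and
    # would otherwise sit below the optimizer's absolute tolerances.  A
    # uniform rescale moves neither the optimum nor the standard errors.
    r_scale = float(np.max(np.abs(iobs) / sigma))
    if r_scale == 0:
        r_scale = 1.0

    def residual(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        return (iv_curve(p, vm, T=T, **conc) - iobs) / sigma / r_scale

    if not free:
        res = residual(np.zeros(0))
        return FitResult(initial, [], {}, {}, {}, res, 0.5 * float(res @ res),
                         0.0, False, 0)

    rng = np.random.default_rng(seed)
    x0 = pack(initial)
    # box the search: +/-3 decades around the guess for positive parameters,
    # +/-1 for the (dimensionless) voltage-partition coefficients; the cycle
    # model has a flat F_c/kd ridge along which unbounded fits run away
    span = np.array([np.log(10.0 ** bound_decades) if n in _LOG_SCALE_FIELDS
                     else 1.0 for n in free])
    lo, hi = x0 - span, x0 + span
    best = None
    for start in range(n_starts):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(scale=0.3, size=x0.shape), lo, hi
        )
        try:
            sol = least_squares(residual, xs, bounds=(lo, hi), method="trf",
                                max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("I-V fit failed to converge from any start")

    jac = best.jac
    jtj = jac.T @ jac
    svals = np.linalg.svd(jtj, compute_uv=False)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf
    ident_warn = cond > 1e10
    if ident_warn:
        warnings.warn(
            "I-V fit Hessian is near-singular: the cycle model is not "
            "practically identifiable for this free-parameter set",
            RuntimeWarning,
            stacklevel=2,
        )
    dof = max(len(vm) - len(free), 1)
    s2 = 2.0 * best.cost / dof
    # full inverse, not a pseudo-inverse: along a nearly flat ridge the
    # truncated small singular values are exactly the directions whose
    # uncertainty must be reported as large
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    fitted = unpack(best.x)
    estimates, std_errors, se_int = {}, {}, {}
    for i, name in enumerate(free):
        est = getattr(fitted, name)
        se_internal = float(np.sqrt(max(cov[i, i], 0.0)))
        estimates[name] = est
        se_int[name] = se_internal
        # delta method: d(exp(x))/dx = exp(x)
        std_errors[name] = se_internal * est if name in _LOG_SCALE_FIELDS else se_internal

    if se_method == "profile" and best.cost > 0:
        # profile out to the 3-sigma rise (delta chi^2 = 9) and report a
        # standard error of one third of that half-width per side: the
        # model's likelihood valleys are locally curved but flatten outward,
        # so scaling the 1-sigma crossing would understate the wide region
        n_sig = 3.0
        target = best.cost + 0.5 * s2 * n_sig**2

        def profiled_cost(i: int, xi: float) -> float:
            others = [j for j in range(len(free)) if j != i]
            if not others:
                x_full = best.x.copy()
                x_full[i] = xi
                r = residual(x_full)
                return 0.5 * float(r @ r)
            xs = best.x[others]
            lo_o, hi_o = lo[others], hi[others]

            def res_sub(xo):
                x_full = best.x.copy()
                x_full[i] = xi
                x_full[others] = xo
                return residual(x_full)

            sol = least_squares(res_sub, np.clip(xs, lo_o, hi_o),
                                bounds=(lo_o, hi_o), method="trf",
                                max_nfev=400)
            return float(sol.cost)

        for i, name in enumerate(free):
            halves = []
            step0 = min(max(np.sqrt(max(cov[i, i], 0.0)), 1e-3), 0.1)
            for direction in (+1.0, -1.0):
                # walk outward until the profiled cost exceeds the target,
                # then bisect the bracketing interval; a single wide probe
                # would step clear over a flat valley and misplace the
                # crossing badly
                step = direction * step0
                prev_x = best.x[i]
                found = None
                for _ in range(16):
                    xi = prev_x + step
                    c = profiled_cost(i, xi)
                    if c >= target:
                        a, b = prev_x, xi
                        for _ in range(6):
                            mid = 0.5 * (a + b)
                            if profiled_cost(i, mid) >= target:
                                b = mid
                            else:
                                a = mid
                        found = abs(0.5 * (a + b) - best.x[i])
                        break
                    prev_x = xi
                    step *= 1.8
                halves.append(found if found is not None
                              else abs(prev_x - best.x[i]))
            se_internal = 0.5 * (halves[0] + halves[1]) / n_sig
            est = estimates[name]
            se_int[name] = se_internal
            std_errors[name] = (se_internal * est
                                if name in _LOG_SCALE_FIELDS else se_internal)
    elif se_method not in ("profile", "gauss-newton"):
        raise ValueError(f"unknown se_method {se_method!r}")

    return FitResult(fitted, list(free), estimates, std_errors, se_int,
                     best.fun, float(best.cost), cond, ident_warn,
                     n_starts)
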