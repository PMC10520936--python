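"""Coupled whole-cell simulation loop.

Per time step, in fixed operator-splitting order:

1. stimulus field E(t);
2. quasi-static potential response -> normal bulk current J_n(theta);
3. membrane ODE:  C_m dVm/dt = J_n - g1 (Vm - V_rest) - I_p  (explicit);
4. pore step (density ODE + cohort radii, whole-cell tension);
5. GMPNP pore fluxes and pore current density I_p (used next step);
6. pump cycle at the local Vm and concentrations -> pump flows and power;
7. concentration update (pores + pump), alternately with the fluxes.

The time step follows a two-phase schedule: a fine step bounded by a
fraction of the pulse width while the drive varies, then geometric growth
(capped at 100x the stimulation step and at the explicit stability bound)
once the field is off.  Runs are deterministic: identical configurations
produce bit-identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atpase as _atp
from . import electroporation as _ep
from . import transport as _tr
from .field_solver import LaplaceSolver, explicit_dt_bound, membrane_conductivity
from .parameters import ParameterBundle
from .stimulus import PulseTrain, field_at, pulse_width


@dataclass
class SimulationPlan:
    """Time horizon, step schedule and recording policy for one run."""

    train: PulseTrain
    t_end: float = 12.3e-9
    dt_stim_fraction: float = 0.05  # dt = fraction * pulse width during drive
    dt_stim: float | None = None  # absolute override of the stimulation step
    dt_growth: float = 1.05  # geometric growth after the drive
    dt_max_factor: float = 100.0  # cap on dt relative to the stimulation dt
    n_frames: int = 1000
    experiment: str = "run"

    def __post_init__(self) -> None:
        if self.t_end <= self.train.t_on:
            raise ValueError("t_end must exceed the stimulation duration t_on")
        if not 0 < self.dt_stim_fraction <= 0.25:
            raise ValueError("dt_stim_fraction must be in (0, 0.25]")


@dataclass
class Trajectory:
    """Recorded time series of one run (per-theta and theta-averaged)."""

    t: np.ndarray  # (n,)
    theta: np.ndarray  # (nt,)
    species: list[str]
    Vm: np.ndarray  # (n, nt) V
    g_m: np.ndarray  # (n, nt) S/m^2, pore conductivity diagnostic
    N: np.ndarray  # (n, nt) 1/m^2 pore density
    A_p: np.ndarray  # (n,) m^2 total pore area
    mean_radius: np.ndarray  # (n, nt) m
    J_pore: np.ndarray  # (n, ns, nt) mol/(m^2 s), outward positive
    J_pump: np.ndarray  # (n, ns, nt) mol/(m^2 s)
    c_i: np.ndarray  # (n, ns, nt) mol/m^3
    c_o: np.ndarray  # (n, ns, nt)
    I_pump_theta: np.ndarray  # (n, nt) A, whole-cell-equivalent at local Vm
    I_pump: np.ndarray  # (n,) A whole-cell pump current
    P_theta: np.ndarray  # (n, nt) W
    config: dict = field(default_factory=dict, repr=False)

    # -- theta-averaged twins (plain arithmetic means over theta nodes) ----
    def avg(self, name: str) -> np.ndarray:
        return _tr.average_unweighted(getattr(self, name), axis=-1)

    @property
    def P_avg(self) -> np.ndarray:
        return self.avg("P_theta")

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-theta record (t, theta, species, ... columns)."""
        n, nt = self.Vm.shape
        rows = []
        for si, sp in enumerate(self.species):
            df = pd.DataFrame({
                "t": np.repeat(self.t, nt),
                "theta": np.tile(self.theta, n),
                "species": sp,
                "J_pore": self.J_pore[:, si, :].ravel(),
                "J_pump": self.J_pump[:, si, :].ravel(),
                "c_i": self.c_i[:, si, :].ravel(),
                "c_o": self.c_o[:, si, :].ravel(),
            })
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        scalar = pd.DataFrame({
            "t": np.repeat(self.t, nt),
            "theta": np.tile(self.theta, n),
            "Vm": self.Vm.ravel(),
            "g_m": self.g_m.ravel(),
            "N": self.N.ravel(),
            "P": self.P_theta.ravel(),
        })
        return out.merge(scalar, on=["t", "theta"])

    def averaged_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "Vm": self.avg("Vm"), "g_m": self.avg("g_m"),
                "N": self.avg("N"), "P": self.P_avg, "I_pump": self.I_pump,
                "A_p": self.A_p}
        for si, sp in enumerate(self.species):
            data[f"J_pore_{sp}"] = _tr.average_unweighted(self.J_pore[:, si, :])
            data[f"J_pump_{sp}"] = _tr.average_unweighted(self.J_pump[:, si, :])
            data[f"c_i_{sp}"] = _tr.average_unweighted(self.c_i[:, si, :])
        return pd.DataFrame(data)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("t", "theta", "Vm", "g_m", "N", "A_p", "mean_radius",
                         "J_pore", "J_pump", "c_i", "c_o", "I_pump_theta",
                         "I_pump", "P_theta"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["species"] = ",".join(self.species)
            f.attrs["config"] = json.dumps(self.config)


class _Recorder:
    def __init__(self, n_frames: int, n_steps_hint: int):
        self.every = max(1, n_steps_hint // n_frames)
        self.rows: list[dict] = []

    def maybe(self, i: int, **kw) -> None:
        if i % self.every == 0:
            self.rows.append(kw)

    def force(self, **kw) -> None:
        self.rows.append(kw)


def run(bundle: ParameterBundle, plan: SimulationPlan) -> Trajectory:
    """Execute the coupled simulation and return the recorded trajectory."""
    g, el, fl = bundle.geometry, bundle.electrical, bundle.flags
    cst = bundle.constants
    T = el.T
    species = bundle.species
    sp_names = [s.name for s in species]
    i_na, i_k = sp_names.index("Na"), sp_names.index("K")

    solver = LaplaceSolver(g, el)
    dt_bound = explicit_dt_bound(solver)
    A_theta, V_i, V_o = _tr.compartment_volumes(g)
    A_cell = g.A_cell
    theta = solver.theta
    nt = g.N_theta

    pores = _ep.PoreState.initial(A_theta, bundle.pore, cst.k_B, T)
    conc = _tr.ConcentrationState.initial(species, nt)
    Vm = np.full(nt, el.V_rest)
    I_p = np.zeros(nt)

    pw = pulse_width(plan.train)
    dt_stim = plan.dt_stim if plan.dt_stim is not None else plan.dt_stim_fraction * pw
    if dt_stim > plan.dt_stim_fraction * pw * (1 + 1e-12):
        raise ValueError("dt_stim must not exceed dt_stim_fraction * pulse width")
    dt_max = min(plan.dt_max_factor * dt_stim, 0.5 * dt_bound)
    if dt_stim > dt_bound:
        raise ValueError(
            f"stimulation step {dt_stim:.3e}s exceeds the explicit stability "
            f"bound {dt_bound:.3e}s; refine the schedule"
        )

    # step-count estimate for the recording stride
    n_stim = int(np.ceil(plan.train.t_on / dt_stim))
    n_post = int(np.ceil((plan.t_end - plan.train.t_on) / dt_max)) + 200
    rec = _Recorder(plan.n_frames, n_stim + n_post)

    pump_scale = A_theta / A_cell  # per-theta share of the whole cell

    def pump_eval(vm, c):
        """Whole-cell-equivalent pump current per theta (A) at local state."""
        rates = _atp.cycle_rates(vm, c.c_i[i_na], c.c_o[i_na],
                                 c.c_i[i_k], c.c_o[i_k], bundle.atpase,
                                 T=T, constants=cst)
        v_cyc = _atp.cycle_rate(rates)
        return _atp.pump_current(v_cyc, bundle.atpase.F_c)

    def pump_flux_density(I_theta_equiv):
        """mol/(m^2 s) per species per theta from the 3:2 stoichiometry."""
        out = np.zeros((len(species), nt))
        base = I_theta_equiv * pump_scale / (cst.q_ele * cst.N_A)  # mol/s /theta
        out[i_na] = 3.0 * base / A_theta
        out[i_k] = -2.0 * base / A_theta
        return out

    def pore_flux_density(c, vm, fp):
        dens = _tr.gmpnp_flux_density(species, c.c_i, c.c_o, vm, g.d_mem, T, cst)
        return _tr.pore_flux(dens, fp, species, cst)

    def record(i, t, force=False):
        if not force and i % rec.every != 0:
            return
        fp = pores.fractional_area()
        sigma_pore = (cst.F**2 / (cst.R_u * T)) * sum(
            s.z**2 * s.D * 0.5 * (conc.c_i[j] + conc.c_o[j])
            for j, s in enumerate(species)
        )
        gm = membrane_conductivity(I_p, Vm, fp=fp, sigma_pore=sigma_pore,
                                   d_mem=g.d_mem)
        row = dict(
            t=t, Vm=Vm.copy(), g_m=np.asarray(gm, float),
            N=pores.N.copy(), A_p=pores.pore_area(),
            mean_radius=pores.mean_radius(),
            J_pore=J_pore_rec.copy(), J_pump=J_pump_rec.copy(),
            c_i=conc.c_i.copy(), c_o=conc.c_o.copy(),
            I_pump_theta=np.asarray(I_theta, float).copy(),
            I_pump=float(np.sum(I_theta * pump_scale)),
            P_theta=np.asarray(P_theta, float).copy(),
        )
        rec.force(**row)

    # initial pump/pore evaluation so the first record row is consistent
    I_theta = pump_eval(Vm, conc)
    P_theta = _atp.power(I_theta, cst, mode=fl.power_mode)
    J_pore_rec = np.zeros((len(species), nt))
    J_pump_rec = pump_flux_density(I_theta)

    t = 0.0
    dt = dt_stim
    i = 0
    record(0, t)
    while t < plan.t_end - 1e-18:
        if t < plan.train.t_on:
            dt = dt_stim
        else:
            dt = min(dt * plan.dt_growth, dt_max)
        dt = min(dt, plan.t_end - t)
        # don't step across the switch-off instant
        if t < plan.train.t_on < t + dt:
            dt = plan.train.t_on - t

        E = float(field_at(plan.train, t))
        J_n = solver.normal_current(E, Vm)
        pump_density = np.zeros(nt)
        if fl.include_pump_current_in_vm:
            pump_density = I_theta * pump_scale / A_theta
        Vm = Vm + dt * (
            J_n - el.g1 * (Vm - el.V_rest) - I_p - pump_density
        ) / el.C_m
        if not np.all(np.isfinite(Vm)):
            raise RuntimeError(f"membrane potential diverged at t={t:.3e}s")

        pores = _ep.step_pores(pores, Vm, dt, bundle.pore, cst, T)
        fp = pores.fractional_area()

        fluxes = pore_flux_density(conc, Vm, fp)
        I_p = fluxes.I_p
        I_theta = pump_eval(Vm, conc)
        P_theta = np.asarray(_atp.power(I_theta, cst, mode=fl.power_mode))
        J_pump_rec = pump_flux_density(I_theta)
        J_pore_rec = fluxes.J_pore
        total = fluxes.J_pore + J_pump_rec

        def flux_fn(state, vm=Vm, fp=fp, I_th=I_theta):
            fs = pore_flux_density(state, vm, fp)
            return fs.J_pore + pump_flux_density(I_th)

        conc = _tr.update_concentrations(
            conc, total, g, dt,
            clamp_extracellular=fl.clamp_extracellular,
            negative_policy=fl.negative_concentration,
            flux_fn=flux_fn,
            volumes=(A_theta, V_i, V_o),
        )

        t += dt
        i += 1
        record(i, t)

    rows = rec.rows
    if rows[-1]["t"] < t - 1e-18:  # ensure the final state is kept
        record(i, t, force=True)
        rows = rec.rows

    def stack(name):
        return np.array([r[name] for r in rows])

    traj = Trajectory(
        t=stack("t"), theta=theta, species=sp_names,
        Vm=stack("Vm"), g_m=stack("g_m"), N=stack("N"), A_p=stack("A_p"),
        mean_radius=stack("mean_radius"),
        J_pore=stack("J_pore"), J_pump=stack("J_pump"),
        c_i=stack("c_i"), c_o=stack("c_o"),
        I_pump_theta=stack("I_pump_theta"), I_pump=stack("I_pump"),
        P_theta=stack("P_theta"),
        config={"bundle": bundle.to_dict(),
                "plan": {**dataclasses.asdict(plan),
                         "train": dataclasses.asdict(plan.train)},
                "experiment": plan.experiment},
    )
    return traj


def detect_pore_activation(traj: Trajectory, threshold: float = 10.0):
    """First time any angle's pore density exceeds threshold x N0.

    Returns the time in seconds, or None if pores never activate.
    ``threshold`` must exceed 1 (the density starts at N0).
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1 (N starts at N0)")
    N0 = traj.config.get("bundle", {}).get("pore", {}).get("N0")
    if N0 is None:
        N0 = traj.N[0].max()
    hit = np.any(traj.N > threshold * N0, axis=1)
    idx = np.argmax(hit)
    if not hit[idx]:
        return None
    return float(traj.t[idx])


def detect_pump_closure(traj: Trajectory, rel_threshold: float = 1e-4,
                        hold: float = 1.0e-9):
    """First time the theta-averaged |pump current| falls below
    rel_threshold x its post-stimulation maximum and stays below for
    ``hold`` seconds.  Returns None while the pump remains open.
    """
    t_on = traj.config.get("plan", {}).get("train", {}).get("t_on", 0.0)
    mask = traj.t >= t_on
    I = np.abs(traj.I_pump)
    peak = I[mask].max()
    if peak <= 0:
        return None
    below = (I < rel_threshold * peak) & mask
    t = traj.t
    start = None
    for i in range(len(t)):
        if below[i]:
            if start is None:
                start = t[i]
            if t[i] - start >= hold:
                return float(start)
        else:
            start = None
    if start is not None and t[-1] - start >= hold:
        return float(start)
    return None


@dataclass
class SweepResult:
    frequencies: np.ndarray
    dc_Na: np.ndarray  # theta-averaged intracellular change at t_end, mol/m^3
    dc_K: np.ndarray
    control_dc_Na: float
    control_dc_K: float
    power_series: list  # (t, P_avg) per frequency
    control_power: tuple


def frequency_sweep(bundle: ParameterBundle, frequencies, plan: SimulationPlan,
                    include_control: bool = True) -> SweepResult:
    """Run the plan at each repetition frequency at fixed duty and amplitude.

    Reports the accumulated theta-averaged intracellular Na+/K+ change at
    t_end and the averaged power series, plus a no-stimulus control.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    # one absolute time step for every frequency (the finest pulse width
    # sets it) so the comparison across frequencies is not confounded by
    # per-frequency discretization error
    dt_common = plan.dt_stim
    if dt_common is None:
        dt_common = plan.dt_stim_fraction * plan.train.duty / float(np.max(freqs))
    dc_na, dc_k, pser = [], [], []
    for f in freqs:
        train = dataclasses.replace(plan.train, f_rep=float(f))
        traj = run(bundle, dataclasses.replace(plan, train=train, dt_stim=dt_common))
        na = _tr.average_unweighted(traj.c_i[:, traj.species_index("Na"), :])
        k = _tr.average_unweighted(traj.c_i[:, traj.species_index("K"), :])
        dc_na.append(na[-1] - na[0])
        dc_k.append(k[-1] - k[0])
        pser.append((traj.t, traj.P_avg))
    if include_control:
        train = dataclasses.replace(plan.train, E0=0.0)
        traj = run(bundle, dataclasses.replace(plan, train=train, dt_stim=dt_common))
        na = _tr.average_unweighted(traj.c_i[:, traj.species_index("Na"), :])
        k = _tr.average_unweighted(traj.c_i[:, traj.species_index("K"), :])
        ctrl = (na[-1] - na[0], k[-1] - k[0], (traj.t, traj.P_avg))
    else:
        ctrl = (np.nan, np.nan, (None, None))
    return SweepResult(freqs, np.array(dc_na), np.array(dc_k),
                       ctrl[0], ctrl[1], pser, ctrl[2])
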