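import dataclasses

import numpy as np
import pytest

from thzpore import (
    PulseTrain,
    SimulationPlan,
    Trajectory,
    detect_pore_activation,
    detect_pump_closure,
    frequency_sweep,
    run,
)


def synthetic_trajectory(t, I_pump, t_on=1.1e-9, N=None, N0=1.5e9):
    """Minimal hand-built trajectory for exercising the detectors."""
    n = len(t)
    nt = 7
    zeros = np.zeros((n, nt))
    zsp = np.zeros((n, 4, nt))
    return Trajectory(
        t=np.asarray(t), theta=np.linspace(0, np.pi, nt),
        species=["Na", "K", "Ca", "Cl"],
        Vm=zeros, g_m=zeros, N=zeros + (N0 if N is None else N),
        A_p=np.zeros(n), mean_radius=zeros,
        J_pore=zsp, J_pump=zsp, c_i=zsp, c_o=zsp,
        I_pump_theta=zeros, I_pump=np.asarray(I_pump), P_theta=zeros,
        config={"plan": {"train": {"t_on": t_on}},
                "bundle": {"pore": {"N0": N0}}},
    )


def test_plan_validation():
    train = PulseTrain(t_on=1.2e-9)
    with pytest.raises(ValueError):
        SimulationPlan(train=train, t_end=1.0e-9)
    with pytest.raises(ValueError):
        SimulationPlan(train=train, t_end=5e-9, dt_stim_fraction=0.5)


def test_rest_is_a_fixed_point(mini_bundle):
    """No field: membrane potential, pore density and pump power hold their
    resting values for the whole run."""
    plan = SimulationPlan(train=PulseTrain(E0=0.0, f_rep=0.5e12, t_on=1.2e-9),
                          t_end=3e-9, n_frames=50, dt_stim_fraction=0.25)
    traj = run(mini_bundle, plan)
    vrest = mini_bundle.electrical.V_rest
    assert np.abs(traj.Vm - vrest).max() < 1e-4
    assert np.abs(traj.N / mini_bundle.pore.N0 - 1).max() < 1e-4
    # resting pump level is steady
    assert np.ptp(traj.P_avg) < 0.01 * abs(traj.P_avg[0]) + 1e-30
    assert detect_pore_activation(traj) is None


def test_determinism_bit_identical(mini_bundle):
    plan = SimulationPlan(train=PulseTrain(E0=5e7, f_rep=0.5e12, t_on=0.2e-9),
                          t_end=0.5e-9, n_frames=40)
    a = run(mini_bundle, plan)
    b = run(mini_bundle, plan)
    np.testing.assert_array_equal(a.Vm, b.Vm)
    np.testing.assert_array_equal(a.c_i, b.c_i)
    np.testing.assert_array_equal(a.N, b.N)
    np.testing.assert_array_equal(a.I_pump, b.I_pump)


def test_reference_run_phenomenology(mini_traj, mini_bundle):
    """Pore fluxes start at zero, rise only after activation late in the
    stimulation, then decay; recorded identities hold at every frame."""
    traj = mini_traj
    act = detect_pore_activation(traj)
    assert act is not None and 0.0 < act < 1.2e-9
    iNa = traj.species_index("Na")
    before = traj.t < 0.8 * act
    after = traj.t > act
    resting = np.abs(traj.J_pore[before, iNa, :]).max()
    active = np.abs(traj.J_pore[after, iNa, :]).max()
    assert active > 1.0 and resting < 1e-5 * active
    # charge-flux identity on the recorded series
    z = np.array([1.0, 1.0, 2.0, -1.0]).reshape(1, -1, 1)
    I_from_J = 96485.33212 * np.sum(z * traj.J_pore, axis=1)
    g_I = traj.g_m * traj.Vm
    np.testing.assert_allclose(
        np.where(np.abs(traj.Vm) > 1e-3, g_I, I_from_J), I_from_J,
        rtol=1e-6, atol=1e-12)
    # pump stoichiometry at every frame: 2 J_Na + 3 J_K = 0
    iK = traj.species_index("K")
    np.testing.assert_allclose(
        2 * traj.J_pump[:, iNa, :] + 3 * traj.J_pump[:, iK, :], 0.0,
        atol=1e-18)


def test_cation_efflux_at_depolarized_pole(mini_traj):
    """During stimulation, cations leave the cell near theta = 0 and enter
    near theta = pi (opposite flux signs across the cell)."""
    traj = mini_traj
    act = detect_pore_activation(traj)
    window = (traj.t > act) & (traj.t < 1.2e-9)
    iNa = traj.species_index("Na")
    assert traj.J_pore[window, iNa, 0].max() > 0  # outward at theta = 0
    assert traj.J_pore[window, iNa, -1].min() < 0  # inward at theta = pi


def test_activation_detector_contract(mini_traj):
    with pytest.raises(ValueError):
        detect_pore_activation(mini_traj, threshold=1.0)
    assert detect_pore_activation(mini_traj, threshold=10.0) <= \
        detect_pore_activation(mini_traj, threshold=1e4)


def test_closure_detector_against_exponential_oracle():
    t = np.linspace(0, 100e-9, 5001)
    rate = 2e8  # 1/s
    I = 1e-11 * np.exp(-np.clip(t - 1.1e-9, 0, None) * rate)
    traj = synthetic_trajectory(t, I)
    thr = 1e-3
    expected = 1.1e-9 + np.log(1.0 / thr) / rate
    got = detect_pump_closure(traj, rel_threshold=thr, hold=1e-9)
    assert got == pytest.approx(expected, rel=0.02)
    # constant current never closes
    traj2 = synthetic_trajectory(t, np.full_like(t, 1e-11))
    assert detect_pump_closure(traj2, rel_threshold=1e-4) is None


def test_sweep_of_length_one_matches_run(mini_bundle):
    plan = SimulationPlan(train=PulseTrain(E0=5e7, f_rep=0.5e12, t_on=0.2e-9),
                          t_end=0.6e-9, n_frames=30)
    res = frequency_sweep(mini_bundle, [0.5e12], plan, include_control=False)
    direct = run(mini_bundle, dataclasses.replace(
        plan, train=dataclasses.replace(plan.train, f_rep=0.5e12),
        dt_stim=plan.dt_stim_fraction * plan.train.duty / 0.5e12))
    iNa = direct.species_index("Na")
    na = direct.c_i[:, iNa, :].mean(axis=1)
    assert res.dc_Na[0] == pytest.approx(na[-1] - na[0], rel=1e-12, abs=1e-18)


def test_dt_refinement_self_convergence(mini_bundle):
    """Halving the stimulation step moves the activation time by < 5% and
    the averaged-power peak by < 5%."""
    mk = lambda frac: SimulationPlan(
        train=PulseTrain(E0=5e7, f_rep=0.5e12, t_on=1.2e-9),
        t_end=2.0e-9, n_frames=200, dt_stim_fraction=frac)
    a = run(mini_bundle, mk(0.05))
    b = run(mini_bundle, mk(0.025))
    ta, tb = detect_pore_activation(a), detect_pore_activation(b)
    assert abs(ta - tb) / tb < 0.05
    assert abs(a.P_avg.max() - b.P_avg.max()) / b.P_avg.max() < 0.05


def test_trajectory_export_round_trip(mini_traj, tmp_path):
    df = mini_traj.averaged_frame()
    assert {"t", "Vm", "P", "I_pump"} <= set(df.columns)
    long = mini_traj.to_frame()
    assert {"t", "theta", "species", "J_pore", "c_i"} <= set(long.columns)
    h5 = tmp_path / "traj.h5"
    mini_traj.save_hdf5(h5)
    import h5py

    with h5py.File(h5) as f:
        np.testing.assert_array_equal(f["Vm"][...], mini_traj.Vm)
        assert f.attrs["species"] == "Na,K,Ca,Cl"
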