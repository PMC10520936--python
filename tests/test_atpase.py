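import dataclasses
import math

import numpy as np
import pytest

from thzpore import (
    CONSTANTS,
    CycleRates,
    cycle_rate,
    cycle_rates,
    default_bundle,
    iv_curve,
    power,
    pump_current,
    pump_flows,
    pump_flows_theta,
)
from thzpore.parameters import AtpaseParams

STANDARD_CONC = dict(c_Na_i=12.0, c_Na_o=145.0, c_K_i=139.0, c_K_o=4.0)


def independent_rates(Vm, c, p, T=310.0):
    """Plain-math re-derivation of the eight composite rates, written
    independently of the vectorized implementation."""
    F, Ru = 96485.33212, 8.31446261815324
    fv = F * Vm / (Ru * T)
    xni = c["c_Na_i"] / p.kd_Nai0 * math.exp(-p.d_Nai * fv)
    xki = c["c_K_i"] / p.kd_Ki0 * math.exp(-p.d_Ki * fv)
    xno = c["c_Na_o"] / p.kd_Nao0 * math.exp(-p.d_Nao * fv)
    xko = c["c_K_o"] / p.kd_Ko0 * math.exp(-p.d_Ko * fv)
    di = (1 + xni) ** 3 + (1 + xki) ** 2 - 1
    do = (1 + xno) ** 3 + (1 + xko) ** 2 - 1
    y = p.c_MgATP / p.kd_MgATP
    return dict(
        R1p=p.k1p * xni**3 / di,
        R2p=p.k2p,
        R3p=p.k3p * xko**2 / do,
        R4p=p.k4p * y / (1 + y),
        R1m=p.k1m * p.c_MgADP,
        R2m=p.k2m * xno**3 / do,
        R3m=p.k3m * p.c_P * 10 ** (3 - p.pH) / (1 + y),
        R4m=p.k4m * xki**2 / di,
    )


def test_composite_rates_match_independent_evaluation(rat_bundle):
    p = rat_bundle.atpase
    for vm in (-0.12, -0.06, 0.0, 0.05, 0.3):
        got = cycle_rates(vm, **STANDARD_CONC, params=p)
        want = independent_rates(vm, STANDARD_CONC, p)
        for name, value in want.items():
            assert float(getattr(got, name)) == pytest.approx(value, rel=1e-12)


def test_rate_boundary_cases(rat_bundle):
    p = rat_bundle.atpase
    # no intracellular Na to bind -> no forward loading step
    r = cycle_rates(-0.06, 0.0, 145.0, 139.0, 4.0, p)
    assert float(r.R1p) == 0.0
    # saturating MgATP -> R4p approaches k4p
    psat = dataclasses.replace(p, c_MgATP=1e9)
    r = cycle_rates(-0.06, **STANDARD_CONC, params=psat)
    assert float(r.R4p) == pytest.approx(p.k4p, rel=1e-6)
    # no external K -> the import branch is shut
    r = cycle_rates(0.0, 12.0, 145.0, 139.0, 0.0, p)
    assert float(r.R3p) == 0.0


def test_cycle_rate_sign_structure():
    ones = {k: np.float64(1.0) for k in
            "R1p R2p R3p R4p R1m R2m R3m R4m".split()}
    # balanced products stall the cycle
    assert cycle_rate(CycleRates(**ones)) == pytest.approx(0.0, abs=1e-15)
    # purely forward rates run forward
    fwd = dict(ones)
    for k in ("R1m", "R2m", "R3m", "R4m"):
        fwd[k] = np.float64(0.0)
    assert cycle_rate(CycleRates(**fwd)) > 0
    with pytest.raises(ZeroDivisionError):
        cycle_rate(CycleRates(**{k: np.float64(0.0) for k in ones}))


def test_pump_current_and_flows_are_exact_stoichiometry():
    v = 37.0
    i1 = pump_current(v, 6e-12)
    assert i1 == pytest.approx(6e-12 * v)
    assert pump_current(v, 1.2e-11) == pytest.approx(2 * i1)
    j_na, j_k = pump_flows(i1, CONSTANTS)
    assert j_na == 3 * i1 / CONSTANTS.q_ele / CONSTANTS.N_A
    assert j_k == -2 * i1 / CONSTANTS.q_ele / CONSTANTS.N_A
    assert 2 * j_na + 3 * j_k == 0.0  # exact, not approximate


def test_per_theta_flows_partition_the_whole_cell(theta7):
    edges = np.concatenate([[0], 0.5 * (theta7[1:] + theta7[:-1]), [np.pi]])
    A_cell = 4 * np.pi * (3.3e-6) ** 2
    A_theta = 2 * np.pi * (3.3e-6) ** 2 * (np.cos(edges[:-1]) - np.cos(edges[1:]))
    I = 3.5e-11
    j_na, j_k = pump_flows_theta(I, A_theta, A_cell, CONSTANTS)
    whole_na, whole_k = pump_flows(I, CONSTANTS)
    assert j_na.sum() == pytest.approx(whole_na, rel=1e-12)
    assert j_k.sum() == pytest.approx(whole_k, rel=1e-12)
    np.testing.assert_allclose(j_k / j_na, -2.0 / 3.0, rtol=1e-12)


def test_power_modes():
    I = 3.7e-11
    assert power(0.0, CONSTANTS) == 0.0
    per_mol = power(I, CONSTANTS, mode="per_molecule")
    lit = power(I, CONSTANTS, mode="literal")
    assert per_mol / lit == pytest.approx(CONSTANTS.N_A)
    assert power(2 * I, CONSTANTS) == pytest.approx(2 * per_mol)
    # the per-molecule accounting puts tens of pA at the 1e-11 W scale
    assert 1e-12 < per_mol < 1e-10
    with pytest.raises(ValueError):
        power(I, CONSTANTS, mode="bogus")


def test_voltage_clamp_not_engaged_below_one_volt(rat_bundle):
    import warnings

    import thzpore.atpase as m

    m._clamp_warned = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", RuntimeWarning)
        cycle_rates(np.linspace(-1.0, 1.0, 101), **STANDARD_CONC,
                    params=rat_bundle.atpase)


def test_rat_iv_monotone_in_physiological_range(rat_bundle):
    vg = np.linspace(-0.12, 0.06, 181)
    I = iv_curve(rat_bundle.atpase, vg, **STANDARD_CONC)
    assert np.all(np.diff(I) >= -1e-30)


def test_pump_runs_forward_at_rest_in_both_cell_types(rat_bundle, gp_bundle):
    for b in (rat_bundle, gp_bundle):
        I = iv_curve(b.atpase, b.electrical.V_rest, **STANDARD_CONC)
        j_na, j_k = pump_flows(I, CONSTANTS)
        assert j_na > 0 and j_k < 0  # Na out, K in


def test_guinea_pig_curve_is_narrower_and_left_shifted(rat_bundle, gp_bundle):
    vg = np.linspace(-0.2, 1.2, 3001)

    def rise_metrics(params):
        I = iv_curve(params, vg, **STANDARD_CONC)
        imax = I.max()
        vpk = vg[I.argmax()]
        rising = vg <= vpk
        v10 = vg[rising][np.argmin(np.abs(I[rising] - 0.1 * imax))]
        v90 = vg[rising][np.argmin(np.abs(I[rising] - 0.9 * imax))]
        return v10, v90 - v10

    rat_v10, rat_width = rise_metrics(rat_bundle.atpase)
    gp_v10, gp_width = rise_metrics(gp_bundle.atpase)
    assert gp_width < rat_width  # narrower shape
    assert gp_v10 < rat_v10  # shifted toward more negative potentials


def test_inhibition_at_overlarge_positive_potentials(rat_bundle):
    """The current falls off beyond its peak, the inhibition seen when the
    induced membrane voltage overshoots during stimulation."""
    p = rat_bundle.atpase
    vg = np.linspace(-0.2, 1.5, 2001)
    I = iv_curve(p, vg, **STANDARD_CONC)
    vpk = vg[I.argmax()]
    assert 0.0 < vpk < 1.0
    assert iv_curve(p, 1.5, **STANDARD_CONC) < 1e-4 * I.max()


def test_iv_zero_crossing_exists_when_backward_can_dominate(rat_bundle):
    """With boosted backward rates the cycle has a reversal potential that a
    sign scan can bracket."""
    p = dataclasses.replace(rat_bundle.atpase, k1m=rat_bundle.atpase.k1m * 3e4,
                            k3m=rat_bundle.atpase.k3m * 3e4)
    vg = np.linspace(-0.2, 0.6, 601)
    I = iv_curve(p, vg, **STANDARD_CONC)
    assert I.min() < 0 < I.max()
    sign_changes = np.nonzero(np.diff(np.sign(I)))[0]
    assert len(sign_changes) >= 1
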