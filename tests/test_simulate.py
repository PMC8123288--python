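"""Integration of the full system over dose schedules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hccdyn as h
from hccdyn.model import ModelParameters


def test_dose_at_cycling():
    sched = h.DoseSchedule.cycled(160.0, 21, 7, end=365)
    assert h.dose_at(sched, 10.0) == 160.0
    assert h.dose_at(sched, 25.0) == 0.0   # off week
    assert h.dose_at(sched, 28.0) == 160.0  # next cycle
    assert h.dose_at(h.DoseSchedule(), 100.0) == 0.0


def test_drug_free_matches_closed_form(case1):
    grid = np.linspace(0.0, 400.0, 101)
    traj = h.simulate(case1, h.DoseSchedule(), h.StateVector(C=1.0, V=1.0), grid)
    cf = h.closed_form_growth(1.0, grid, case1)
    assert np.max(np.abs(traj.C[1:] - cf[1:]) / cf[1:]) < 1e-6


def test_steady_states_at_constant_dose(case1):
    """F and V settle at their fixed points within 0.1% after ten lifetimes."""
    sched = h.DoseSchedule.constant(600.0)
    grid = np.linspace(0.0, 250.0, 251)
    traj = h.simulate(case1, sched, h.pretherapy_state(case1, 1.78e6), grid)
    G = h.steady_state_drug(case1.mu1, case1.mu2, 600.0)
    assert traj.F[-1] == pytest.approx(G, rel=1e-3)
    assert traj.G[-1] == pytest.approx(G, rel=1e-3)
    V_ss = case1.alpha2 * h.epsilon_vascular(G, case1.theta1) / (
        case1.alpha2 + case1.alpha3 * G / case1.g_ref)
    assert traj.V[-1] == pytest.approx(V_ss, rel=1e-3)
    assert traj.eps_vascular[-1] == pytest.approx(0.2256, abs=2e-4)


def test_pivka_decomposition_linearity(case1):
    """Spike/toxicity pools add linearly and never feed back on C or P_c."""
    p_on = case1.replace(sigma_sp=0.3, t_sp=7.0, tau_sp=14.0, pi4=15.0, pi5=1.52)
    sched = h.DoseSchedule.constant(400.0)
    init = h.pretherapy_state(case1, 1.78e6)
    grid = np.linspace(0.0, 120.0, 121)
    full = h.simulate(p_on, sched, init, grid, P0=3e4)
    off = h.simulate(case1, sched, init, grid, P0=3e4)
    # the two runs take different step sequences; agreement is limited by
    # the integration tolerance, not by the decomposition itself
    assert np.allclose(full.P_c, off.P_c, rtol=1e-6, atol=1e-9)
    assert np.allclose(full.C, off.C, rtol=1e-6)
    assert np.allclose(full.pivka_total, full.P_c + full.P_sp + full.P_tox)
    # spike pool stays empty until its onset delay, then fills
    assert np.all(full.P_sp[grid <= 7.0] == 0.0)
    assert np.all(full.P_sp[grid > 8.0] > 0) and np.all(full.P_tox[2:] > 0)
    # components disabled -> observed PIVKA-II is the cell pool alone
    assert np.allclose(off.pivka_total, off.P_c)


def test_grid_refinement_stability(case1):
    sched = h.DoseSchedule.constant(600.0)
    init = h.pretherapy_state(case1, 1.78e6)
    grid = np.linspace(0.0, 180.0, 61)
    c1 = h.simulate(case1, sched, init, grid, rtol=1e-8, atol=1e-10).C[-1]
    c2 = h.simulate(case1, sched, init, grid, rtol=5e-9, atol=5e-11).C[-1]
    assert abs(c1 - c2) / c2 < 1e-5


def test_monotone_dose_response(case1):
    reductions = [
        h.kinetic_summary(case1, d)["neoangiogenesis_reduction_pct"]
        for d in (0, 100, 200, 400, 600, 800)
    ]
    assert reductions[0] == 0.0
    assert all(a < b for a, b in zip(reductions, reductions[1:]))


def test_regorafenib_cycling_periodicity(cases):
    """After the transient, F(t) is periodic with the 28-day cycle period."""
    p = cases[3].params
    sched = h.DoseSchedule.cycled(160.0, 21, 7, end=560)
    grid = np.arange(0.0, 560.5, 1.0)
    traj = h.simulate(p, sched, h.pretherapy_state(p, 5.79e5), grid)
    tail = traj.F[400:500]
    shifted = traj.F[428:528]
    assert np.max(np.abs(tail - shifted)) < 1e-8
    assert tail.max() / tail.min() > 5  # genuine on/off fluctuation


def test_kinetic_summary_printed_reductions(cases):
    s1 = h.kinetic_summary(cases[1].params, 600.0)
    assert s1["neoangiogenesis_reduction_pct"] == pytest.approx(77.4, abs=0.2)
    assert s1["replication_reduction_pct"] == pytest.approx(13.5, abs=0.2)
    s2 = h.kinetic_summary(cases[2].params, 800.0)
    assert s2["neoangiogenesis_reduction_pct"] == pytest.approx(50.9, abs=0.2)
    assert s2["replication_reduction_pct"] == pytest.approx(9.4, abs=0.2)
    s0 = h.kinetic_summary(cases[1].params, 0.0)
    assert s0["neoangiogenesis_reduction_pct"] == 0.0
    assert s0["replication_reduction_pct"] == 0.0
    assert s1["mean_lifetime_days"]["cancer_cells"] == pytest.approx(9.1, abs=0.05)


def test_counterfactual_recurrence_flags(case1, residual_state):
    taper = h.DoseSchedule([(0.0, 90.0, 200.0), (90.0, 1e9, 100.0)])
    with_a3 = h.counterfactual_dose_response(case1, [taper], residual_state)[0]
    without = h.counterfactual_dose_response(case1, [taper], residual_state,
                                             alpha3=0.0)[0]
    untreated = h.counterfactual_dose_response(case1, [h.DoseSchedule()],
                                               residual_state)[0]
    assert not with_a3.recurrence
    assert without.recurrence
    assert untreated.recurrence
    with pytest.raises(ValueError):
        h.counterfactual_dose_response(case1, [], residual_state)


def test_simulate_input_validation(case1):
    init = h.StateVector(C=1.0)
    with pytest.raises(ValueError):
        h.simulate(case1, h.DoseSchedule(), init, [0.0])
    with pytest.raises(ValueError):
        h.simulate(case1, h.DoseSchedule(), init, [0.0, 10.0, 5.0])


def test_trajectory_export_columns(case1):
    grid = np.linspace(0.0, 30.0, 31)
    traj = h.simulate(case1, h.DoseSchedule.constant(400.0),
                      h.pretherapy_state(case1, 1e5), grid)
    df = traj.to_frame()
    assert list(df.columns) == [
        "time_days", "C", "V", "AFP", "PIVKA_total", "PIVKA_c", "PIVKA_sp",
        "PIVKA_tox", "F", "F_del", "dose_mg_day"]
    assert np.all(df["PIVKA_total"] >= df["PIVKA_c"])
    assert df["dose_mg_day"].iloc[-1] == 400.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    xi1=st.floats(0.1, 0.5), xi2=st.floats(0.6, 0.99),
    theta1=st.floats(0.0, 500.0), psi1=st.floats(0.0, 100.0),
    alpha3=st.floats(0.0, 0.4), dose=st.floats(0.0, 800.0),
)
def test_positivity_under_random_parameters(xi1, xi2, theta1, psi1, alpha3, dose):
    """No state component ever goes negative for non-negative inputs."""
    p = ModelParameters(
        xi1=xi1, xi2=xi2, xi4=0.11, omega1=2e-3, omega2=0.1,
        pi1=2.5e-4, pi2=1.1, pi3=0.3, mu1=1.3e-5, mu2=0.5,
        theta1=theta1, psi1=psi1, alpha2=4.2e-3, alpha3=alpha3,
        sigma_sp=0.1, t_sp=5.0, tau_sp=10.0, pi4=5.0, pi5=1.2,
    )
    grid = np.linspace(0.0, 150.0, 31)
    traj = h.simulate(p, h.DoseSchedule.constant(dose),
                      h.pretherapy_state(p, 1e5), grid,
                      P0=100.0, rtol=1e-6, atol=1e-9)
    for name in ("C", "V", "A", "P_c", "P_sp", "P_tox", "F", "G"):
        assert np.all(getattr(traj, name) >= 0.0)
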