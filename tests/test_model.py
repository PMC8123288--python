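"""Rate laws, drug-effectiveness algebra and closed-form growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hccdyn as h
from hccdyn.model import ModelParameters, pretherapy_state


@pytest.mark.parametrize("func,G,coef,expected", [
    (h.epsilon_vascular, 0.0, 220.0, 1.0),
    (h.epsilon_vascular, 0.0156, 220.0, 0.2256),
    (h.epsilon_vascular, 0.0208, 50.0, 0.4902),
    (h.epsilon_replication, 0.0, 10.0, 1.0),
    (h.epsilon_replication, 0.0156, 10.0, 0.8651),
    (h.epsilon_replication, 0.0208, 5.0, 0.9058),
])
def test_effectiveness_fractions(func, G, coef, expected):
    assert func(G, coef) == pytest.approx(expected, abs=2e-4)


@pytest.mark.parametrize("func", [h.epsilon_vascular, h.epsilon_replication])
def test_effectiveness_rejects_negative_inputs(func):
    with pytest.raises(ValueError):
        func(-0.01, 10.0)
    with pytest.raises(ValueError):
        func(0.01, -1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(G=st.floats(0, 10), theta=st.floats(0, 1e4))
def test_effectiveness_algebra(G, theta):
    """eps in (0, 1], eps(0) = 1, and 1 - eps = theta*G/(1 + theta*G) exactly."""
    eps = h.epsilon_vascular(G, theta)
    assert 0 < eps <= 1
    assert 1 - eps == pytest.approx(theta * G / (1 + theta * G), abs=1e-12)
    # strictly decreasing in G once theta*G is above rounding noise
    if theta * G > 1e-12:
        assert h.epsilon_vascular(G * 2, theta) < eps


def test_steady_state_drug():
    assert h.steady_state_drug(1.3e-5, 0.5, 400) == pytest.approx(0.0104)
    assert h.steady_state_drug(1.3e-5, 0.5, 0) == 0.0
    assert h.steady_state_drug(1.3e-5, 0.5, 600) == pytest.approx(0.0156)
    with pytest.raises(ValueError):
        h.steady_state_drug(1.3e-5, 0.0, 400)


@pytest.mark.parametrize("k,expected", [
    (0.11, 9.0909), (0.0042, 238.095), (1.0, 1.0),
])
def test_mean_lifetime(k, expected):
    assert h.mean_lifetime(k) == pytest.approx(expected, rel=1e-4)
    with pytest.raises(ValueError):
        h.mean_lifetime(0.0)


def test_growth_rate(case1):
    # small-tumor limit: per-capita rate -> xi1 - xi4 = 0.25/day (2.77-day doubling)
    assert h.growth_rate(1.0, case1) == pytest.approx(0.25)
    r = h.growth_rate(1.78e6, case1)
    assert math.log(2) / r == pytest.approx(29.7, abs=0.1)
    cap = case1.carrying_capacity
    assert h.growth_rate(cap, case1) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        h.growth_rate(0.0, case1)


def test_closed_form_growth(case1):
    assert h.closed_form_growth(123.0, 0.0, case1) == pytest.approx(123.0, rel=1e-12)
    # fixed point of the substituted linear ODE
    cap = (0.36 / 0.11) ** (1 / (1 - 0.931))
    assert h.closed_form_growth(1.0, 1e5, case1) == pytest.approx(cap, rel=1e-6)
    assert h.closed_form_growth(1.0, 181.476, case1) == pytest.approx(1.78e6, rel=1e-4)
    with pytest.raises(ValueError):
        h.closed_form_growth(1.0, 10.0, case1.replace(xi2=1.0))


def test_time_to_reach(case1):
    assert h.time_to_reach(5.0, 5.0, case1) == 0.0
    t = h.time_to_reach(1.0, 1.78e6, case1)
    assert t == pytest.approx(181.48, abs=0.05)
    # round trip with the closed form
    assert h.closed_form_growth(1.0, t, case1) == pytest.approx(1.78e6, rel=1e-9)
    # exponential limit as xi2 -> 1
    p = case1.replace(xi2=0.99999)
    assert h.time_to_reach(1.0, 2.0, p) == pytest.approx(
        math.log(2) / (p.xi1 - p.xi4), rel=1e-3)
    with pytest.raises(ValueError):
        h.time_to_reach(1.0, case1.carrying_capacity * 2, case1)


def test_tox_production_rate():
    assert h.tox_production_rate(0.0, 0.01, 15.0, 1.52) == 0.0
    assert h.tox_production_rate(50.0, 0.01, 0.0, 1.52) == 0.0
    assert h.tox_production_rate(10.0, 0.0028, 15.0, 1.52) == pytest.approx(1.39, abs=0.01)
    assert h.tox_production_rate(-5.0, 0.01, 15.0, 1.52) == 0.0


def test_spike_production_rate(case1):
    p = case1.replace(sigma_sp=0.5, t_sp=10.0, tau_sp=14.0)
    assert h.spike_production_rate(5.0, 100.0, p) == 0.0
    assert h.spike_production_rate(10.0, 100.0, p) == 0.0
    # pulse peak is exactly sigma_sp * P0 * R at t = t_sp + tau_sp
    assert h.spike_production_rate(24.0, 100.0, p) == pytest.approx(50.0)
    assert h.spike_production_rate(24.0, 100.0, case1) == 0.0  # sigma_sp = 0


def test_rhs_drug_free_reduces_to_growth_law(case1):
    C = 1.78e6
    A_ss = case1.omega1 * C / case1.omega2
    y = [C, 1.0, A_ss, 10.0, 0.0, 0.0, 0.0, 0.0]
    dy = h.rhs(0.0, y, case1, h.DoseSchedule(), P0=0.0)
    assert dy[0] == pytest.approx(case1.xi1 * C ** case1.xi2 - case1.xi4 * C)
    assert dy[1] == pytest.approx(0.0, abs=1e-15)  # V in equilibrium
    assert dy[2] == pytest.approx(0.0, abs=1e-9)   # AFP quasi-steady


def test_rhs_spike_and_tox_stay_zero_when_disabled(case2):
    # anti-angiogenic response without ischemic spike or toxicity terms
    assert case2.sigma_sp == 0 and case2.pi4 == 0
    y = [3.17e6, 1.0, 100.0, 100.0, 0.0, 0.0, 0.01, 0.01]
    dy = h.rhs(30.0, y, case2, 800.0, P0=1e5)
    assert dy[4] == 0.0 and dy[5] == 0.0


def test_estimate_initial_cells():
    assert h.estimate_initial_cells(139, 0.5, 2.561e4) == pytest.approx(1.78e6, rel=1e-3)
    assert h.estimate_initial_cells(0.1, 0.5, 2.561e4) == pytest.approx(1.28e3, rel=1e-2)
    assert h.estimate_initial_cells(1, 1, 1) == 1.0
    with pytest.raises(ValueError):
        h.estimate_initial_cells(-1, 0.5, 1e4)
    with pytest.raises(ValueError):
        h.estimate_initial_cells(10, 1.5, 1e4)


def test_tumor_vascular_index():
    assert h.tumor_vascular_index(80, 60) == 20
    assert h.tumor_vascular_index(60, 60) == 0
    assert h.tumor_vascular_index(50, 65) == -15  # hypo-vascular lesion


@pytest.mark.parametrize("changes", [
    {"xi4": 0.0}, {"omega2": -0.1}, {"xi2": 1.4}, {"xi2": 0.0},
    {"pi2": 1.5}, {"mu2": 0.0}, {"theta1": -1.0}, {"g_ref": 0.0},
])
def test_parameter_validation(case1, changes):
    with pytest.raises(ValueError):
        case1.replace(**changes)


def test_parameter_dict_round_trip(case1):
    d = case1.to_dict()
    assert ModelParameters.from_dict(d) == case1
    with pytest.raises(ValueError, match="unknown"):
        ModelParameters.from_dict({**d, "xi9": 1.0})
    bad = dict(d)
    bad.pop("xi1")
    with pytest.raises(ValueError, match="xi1"):
        ModelParameters.from_dict(bad)


def test_state_vector_basics():
    s = h.StateVector(C=10, V=1, A=5, P_c=2, P_sp=1, P_tox=0.5, F=0.01, G=0.005)
    assert s.pivka_total == pytest.approx(3.5)
    assert np.allclose(h.StateVector.from_array(s.as_array()).as_array(), s.as_array())
    with pytest.raises(ValueError):
        h.StateVector(C=-1)


def test_dose_schedule_invariants():
    with pytest.raises(ValueError):
        h.DoseSchedule([(0, 10, 400), (5, 15, 200)])  # overlap
    with pytest.raises(ValueError):
        h.DoseSchedule([(0, 10, -5)])
    with pytest.raises(ValueError):
        h.DoseSchedule([(10, 10, 100)])
    s = h.DoseSchedule([(0, 30, 400), (30, 60, 200)])
    assert s.dose_at(-0.5) == 0.0
    assert s.dose_at(29.999) == 400.0
    assert s.dose_at(30.0) == 200.0  # half-open [start, end)
    assert s.dose_at(60.0) == 0.0


def test_pretherapy_state_matches_growth(case1):
    """Quasi-steady biomarker levels are consistent with the growing source."""
    st0 = pretherapy_state(case1, 1.78e6)
    g = h.growth_rate(1.78e6, case1)
    assert st0.A == pytest.approx(case1.omega1 * 1.78e6 / (case1.omega2 + g))
    assert st0.V == 1.0 and st0.F == 0.0
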