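import numpy as np
import pytest

import hccdyn as h


@pytest.fixture(scope="session")
def cases():
    return h.load_case_fixtures()


@pytest.fixture(scope="session")
def case1(cases):
    return cases[1].params


@pytest.fixture(scope="session")
def case2(cases):
    return cases[2].params


@pytest.fixture(scope="session")
def noise_free_patient(case1):
    """Noise-free synthetic Case-1-like patient at 600 mg/day."""
    noise = h.NoiseModel(cv_afp=0.0, cv_pivka=0.0, jitter_days=0.0, seed=1)
    return h.generate_patient(
        case1, h.DoseSchedule.constant(600.0), h.default_sampling_plan(),
        noise, c0=1.78e6)


@pytest.fixture(scope="session")
def residual_state(case1):
    """Minimal-residual-disease state at the 400 mg/day treated steady state."""
    G = h.steady_state_drug(case1.mu1, case1.mu2, 400.0)
    ev = h.epsilon_vascular(G, case1.theta1)
    V = case1.alpha2 * ev / (case1.alpha2 + case1.alpha3 * G / case1.g_ref)
    C = 1e3
    return h.StateVector(
        C=C, V=V, A=case1.omega1 * C / case1.omega2,
        P_c=case1.pi1 * C ** case1.pi2 / case1.pi3, F=G, G=G)
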