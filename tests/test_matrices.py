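import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import famcr
from famcr.params import DepartureModel
from famcr.states import (A, A01, A02, A11, A12, AS1, AS2, D, SA4, SA5,
                          N_SDPRIME, N_SPRIME, N_STATES, SPACE)
from conftest import random_parameters

IP = SPACE.idx_Sprime
ID = SPACE.idx_Sdprime


def brute_force_transition(params):
    """Path enumeration over S -> S -> S' -> S'' -> S, no matrix algebra."""
    Phi = famcr.build_phi(params)
    P1 = famcr.build_psi1(params)
    P2 = famcr.build_psi2(params)
    P3 = famcr.build_psi3(params)
    out = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            tot = 0.0
            for m in range(N_STATES):
                for a in range(N_SPRIME):
                    for b in range(N_SDPRIME):
                        tot += Phi[i, m] * P1[m, a] * P2[a, b] * P3[b, j]
            out[i, j] = tot
    return out


@pytest.mark.parametrize("seed", range(5))
def test_all_matrices_row_stochastic(seed):
    params = random_parameters(np.random.default_rng(seed),
                               kind="seasonal" if seed % 2 else "constant")
    mats = [famcr.build_phi(params), famcr.build_psi1(params),
            famcr.build_psi2(params), famcr.build_psi3(params),
            famcr.build_transition(params), famcr.build_e1(params, 97.0),
            famcr.build_e2(params), famcr.build_event(params, 97.0)]
    shapes = [(12, 12), (12, 13), (13, 16), (16, 12), (12, 12), (12, 12),
              (12, 12), (12, 12)]
    for M, shape in zip(mats, shapes):
        assert M.shape == shape
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)


@pytest.mark.parametrize("seed", range(8))
def test_transition_equals_path_enumeration(seed):
    params = random_parameters(np.random.default_rng(100 + seed))
    np.testing.assert_allclose(famcr.build_transition(params),
                               brute_force_transition(params), atol=1e-13)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), d=st.floats(80.0, 130.0))
def test_dead_state_absorbing_and_silent(seed, d):
    """D is absorbing under Psi and emits only the nonobservation event."""
    params = random_parameters(np.random.default_rng(seed))
    Psi = famcr.build_transition(params)
    assert Psi[D, D] == 1.0 and Psi[D, :D].sum() == 0.0
    E = famcr.build_event(params, d)
    assert E[D, 11] == 1.0 and E[D, :11].sum() == 0.0
    np.testing.assert_allclose(Psi.sum(axis=1), 1.0, atol=1e-12)


def test_survival_matrix_entries(truth):
    Phi = famcr.build_phi(truth)
    assert Phi[A01, A01] == pytest.approx(0.9)
    assert Phi[A01, D] == pytest.approx(0.1)
    # dead state is absorbing
    assert Phi[D, D] == 1.0 and Phi[D, :D].sum() == 0.0
    ident = famcr.build_phi(truth.with_values(
        {f"phi{i}": 1.0 for i in range(1, 12)}))
    np.testing.assert_array_equal(ident, np.eye(12))


def test_offspring_survival_matrix_entries(truth):
    P1 = famcr.build_psi1(truth)  # s2=0.55, s4=0.75, kappa=0
    assert P1[A02, IP["A12"]] == pytest.approx(0.3025)
    assert P1[A02, IP["A11"]] == pytest.approx(0.495)
    assert P1[A02, IP["A0-"]] == pytest.approx(0.2025)
    assert P1[A12, IP["AS2"]] == pytest.approx(0.5625)
    assert P1[A12, IP["A1-"]] == pytest.approx(0.0625)
    assert P1[SA4, IP["SA5"]] == 1.0 and P1[SA4, IP["A"]] == 0.0


def test_breeding_matrix_entries(truth):
    P2 = famcr.build_psi2(truth)  # beta1=0.5
    assert P2[IP["A0-"], ID["B/A0-"]] == pytest.approx(0.5)
    assert P2[IP["A11"], ID["A11"]] == 1.0  # pass-through row
    certain = famcr.build_psi2(truth.with_values({"beta3": 1.0}))
    assert certain[IP["I/AS1"], ID["NB/AS"]] == 0.0


def test_litter_size_matrix_entries(truth):
    P3 = famcr.build_psi3(truth)  # gamma4=0.7
    assert P3[ID["B/A"], A01] == pytest.approx(0.7)
    assert P3[ID["B/A"], A02] == pytest.approx(0.3)
    assert P3[ID["NB/A"], A] == 1.0
    twins = famcr.build_psi3(truth.with_values({"gamma1": 0.0}))
    assert twins[ID["B/A0-"], A02] == 1.0


def test_transition_hand_derived_entries():
    rng = np.random.default_rng(3)
    base = random_parameters(rng)
    p1 = base.with_values({**{f"phi{i}": 1.0 for i in range(1, 12)},
                           "s3": 0.8})
    assert famcr.build_transition(p1)[A11, AS1] == pytest.approx(0.8)
    p2 = base.with_values({**{f"phi{i}": 1.0 for i in range(1, 12)},
                           "s1": 0.6, "beta1": 0.5, "gamma1": 0.4})
    # only the failed-cub-litter path returns to a singleton-cub state
    assert famcr.build_transition(p2)[A01, A01] == pytest.approx(0.4 * 0.5 * 0.4)
    p0 = base.with_values({f"phi{i}": 0.0 for i in range(1, 12)})
    T0 = famcr.build_transition(p0)
    np.testing.assert_allclose(T0[:, D], 1.0)


def test_departure_probability_models():
    const = DepartureModel(kind="constant", alpha0=0.5)
    assert famcr.departure_probability(const, 100) == pytest.approx(0.5)
    seas = DepartureModel(kind="seasonal")
    assert famcr.departure_probability(seas, 80.0) == pytest.approx(0.40, abs=1e-10)
    assert famcr.departure_probability(seas, 130.0) == pytest.approx(0.80, abs=1e-10)
    flat = DepartureModel(kind="seasonal", intercept=0.3, slope=0.0)
    d = np.array([80.0, 100.0, 130.0])
    assert np.ptp(famcr.departure_probability(flat, d)) == 0.0


@pytest.mark.parametrize("alpha,expected", [
    (0.5, {(AS2, 8): 0.5, (AS2, 9): 0.25, (AS2, 10): 0.25}),
    (0.0, {(AS1, 8): 1.0}),
    (1.0, {(AS2, 10): 1.0}),
])
def test_observation_class_matrix_limits(truth, alpha, expected):
    params = truth.with_values({"alpha0": alpha})
    E1 = famcr.build_e1(params, 100.0)
    for (i, j), v in expected.items():
        assert E1[i, j] == pytest.approx(v)


def test_simultaneous_sibling_departure(truth):
    dep = DepartureModel(kind="constant", alpha0=0.3,
                         simultaneous_siblings=True)
    params = famcr.ParameterSet(phi=truth.phi, s=truth.s, kappa=truth.kappa,
                                beta=truth.beta, gamma=truth.gamma,
                                p=truth.p, pi=truth.pi, departure=dep)
    E1 = famcr.build_e1(params, 100.0)
    assert E1[AS2, 8] == 0.0
    assert E1[AS2, 9] == pytest.approx(0.7)
    assert E1[AS2, 10] == pytest.approx(0.3)


def test_detection_matrix(truth):
    params = truth.with_values({f"p{i}": 0.25 for i in range(1, 12)})
    E2 = famcr.build_e2(params)
    assert E2[4, 4] == pytest.approx(0.25)
    assert E2[4, 11] == pytest.approx(0.75)
    assert E2[11, 11] == 1.0 and E2[11, :11].sum() == 0.0
    sure = famcr.build_e2(truth.with_values({f"p{i}": 1.0 for i in range(1, 12)}))
    np.testing.assert_array_equal(sure[:11, :11], np.eye(11))


def test_composite_event_matrix(truth):
    params = truth.with_values({**{f"p{i}": 0.7 for i in range(1, 12)},
                                "alpha0": 0.5})
    E = famcr.build_event(params, 100.0)
    assert E[A11, 6] == pytest.approx(0.7)      # event 7
    assert E[A11, 11] == pytest.approx(0.3)
    assert E[AS1, 8] == pytest.approx(0.35)     # hand product of E1.E2
    assert E[AS1, 10] == pytest.approx(0.35)
    assert E[AS1, 11] == pytest.approx(0.3)
    assert E[D, 11] == 1.0


@pytest.mark.parametrize("seed", range(4))
def test_shared_detection_makes_noncapture_date_free(seed):
    """With shared p the event-12 column is 1-p for every alive state."""
    rng = np.random.default_rng(200 + seed)
    params = random_parameters(rng, kind="seasonal")
    p = 0.43
    params = params.with_values({f"p{i}": p for i in range(1, 12)})
    for d in (80.0, 105.0, 130.0):
        E = famcr.build_event(params, d)
        np.testing.assert_allclose(E[:11, 11], 1.0 - p, atol=1e-12)
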