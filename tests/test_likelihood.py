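"""Forward-algorithm likelihood against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

import famcr
from famcr.data import Dataset, FamilyHistory
from famcr.likelihood import DEFAULT_NONCAPTURE_DATE
from famcr.matrices import build_e1, build_event, build_transition
from famcr.states import A, A01, A11, AS1, AS2, SA4, event_to_index
from conftest import random_parameters


def enumeration_loglik(history, params, T,
                       noncapture_date=DEFAULT_NONCAPTURE_DATE):
    """Sum over all 12^n latent state sequences (independent oracle)."""
    recs = {o: (d, e) for o, d, e in history.records}
    occs = list(range(history.first_occasion, T + 1))
    Psi = build_transition(params)
    pi_full = np.append(params.pi, 0.0)

    def emit_col(o):
        d, e = recs.get(o, (None, 0))
        if e == 0:
            return build_event(params, noncapture_date)[:, 11]
        c = event_to_index(e)
        return build_e1(params, d)[:, c] * params.p[c]

    cols = [emit_col(o) for o in occs]
    d1, e1 = recs[occs[0]]
    init = pi_full * build_e1(params, d1)[:, event_to_index(e1)]
    total = 0.0
    for seq in itertools.product(range(12), repeat=len(occs)):
        w = init[seq[0]]
        for i in range(1, len(occs)):
            w *= Psi[seq[i - 1], seq[i]] * cols[i][seq[i]]
        total += w
    return np.log(total) if total > 0 else -np.inf


def random_history(rng, T):
    first = int(rng.integers(1, T + 1))
    recs = []
    for o in range(first, T + 1):
        if o == first or rng.random() < 0.6:
            recs.append((o, float(rng.uniform(80, 130)),
                         int(rng.integers(1, 12))))
        else:
            recs.append((o, None, 0))
    return FamilyHistory("fam", tuple(recs))


@pytest.mark.parametrize("seed", range(12))
def test_forward_matches_state_sequence_enumeration(seed):
    rng = np.random.default_rng(seed)
    params = random_parameters(rng, kind="seasonal" if seed % 2 else "constant")
    h = random_history(rng, T=int(rng.integers(2, 5)))
    T = h.records[-1][0]
    a = famcr.forward_loglik(h, params, T)
    b = enumeration_loglik(h, params, T)
    if np.isinf(b):
        assert np.isinf(a)
    else:
        assert a == pytest.approx(b, abs=1e-9)


def test_initial_event_probability_unique_class(truth):
    v = famcr.initial_event_probability(truth, event=7, d=100.0)
    expected = np.zeros(12)
    expected[A11] = 1.0 / 11.0
    np.testing.assert_allclose(v, expected)


def test_initial_event_probability_ambiguous_class(truth):
    params = truth.with_values({"alpha0": 0.5})
    v = famcr.initial_event_probability(params, event=11, d=100.0)
    pi = params.pi
    assert v[A] == pytest.approx(pi[A])
    assert v[AS1] == pytest.approx(pi[AS1] * 0.5)
    assert v[AS2] == pytest.approx(pi[AS2] * 0.25)
    assert v.sum() == pytest.approx(pi[A] + 0.5 * pi[AS1] + 0.25 * pi[AS2])


def test_initial_event_rejects_nonobservation(truth):
    with pytest.raises(ValueError):
        famcr.initial_event_probability(truth, event=0, d=100.0)


def test_forward_hand_derived_values():
    rng = np.random.default_rng(5)
    base = random_parameters(rng)
    ones = {f"phi{i}": 1.0 for i in range(1, 12)}
    ps = {f"p{i}": 1.0 for i in range(1, 12)}
    params = base.with_values({**ones, **ps, "s3": 0.8, "alpha0": 0.5},
                              pi=np.full(11, 1 / 11))
    h = FamilyHistory("f", ((1, 100.0, 7), (2, 100.0, 9)))
    assert famcr.forward_loglik(h, params, 2) == pytest.approx(
        np.log(1 / 11 * 0.8 * 0.5))
    params2 = base.with_values({**ones, **ps, "s1": 0.6, "beta1": 0.5},
                               pi=np.full(11, 1 / 11))
    h2 = FamilyHistory("f", ((1, 100.0, 5), (2, 100.0, 11)))
    # post-first-capture factor is (1-s1)(1-beta1)
    assert famcr.forward_loglik(h2, params2, 2) == pytest.approx(
        np.log(1 / 11 * 0.4 * 0.5))


def test_single_capture_history_is_initial_term_only(truth):
    h = FamilyHistory("f", ((3, 90.0, 3),))  # event 3 -> state SA4 uniquely
    assert famcr.forward_loglik(h, truth, 3) == pytest.approx(
        np.log(truth.pi[SA4]))


def test_impossible_history_returns_neg_inf(truth):
    # kappa=0: a 4-year-old subadult cannot be an adult with cubs next year
    h = FamilyHistory("f", ((1, 90.0, 3), (2, 90.0, 5)))
    assert famcr.forward_loglik(h, truth, 2) == -np.inf


def test_dataset_loglik_sums_and_is_order_invariant(truth, rng):
    h1 = random_history(rng, 4)
    h2 = random_history(rng, 4)
    d12 = Dataset((FamilyHistory("a", h1.records),
                   FamilyHistory("b", h2.records)), 4)
    d21 = Dataset((FamilyHistory("x", h2.records),
                   FamilyHistory("y", h1.records)), 4)
    ll = famcr.dataset_loglik(d12, truth)
    assert ll == pytest.approx(famcr.dataset_loglik(d21, truth), abs=1e-10)
    assert ll == pytest.approx(famcr.forward_loglik(h1, truth, 4)
                               + famcr.forward_loglik(h2, truth, 4), abs=1e-10)
    twice = Dataset((FamilyHistory("a", h1.records),
                     FamilyHistory("b", h1.records)), 4)
    assert famcr.dataset_loglik(twice, truth) == pytest.approx(
        2 * famcr.forward_loglik(h1, truth, 4), abs=1e-10)


def test_loglik_nonpositive(truth, rng):
    for _ in range(5):
        h = random_history(rng, 5)
        assert famcr.forward_loglik(h, truth, 5) <= 0.0


@pytest.mark.parametrize("kind", ["constant", "seasonal"])
def test_total_probability_over_event_sequences(kind):
    """Conditional on first capture, the event distribution sums to 1."""
    rng = np.random.default_rng(77)
    params = random_parameters(rng, kind=kind)
    T, d = 3, 100.0
    total = 0.0
    for e1 in range(1, 12):
        for e2 in range(0, 12):
            for e3 in range(0, 12):
                recs = [(1, d, e1),
                        (2, d, e2) if e2 else (2, None, 0),
                        (3, d, e3) if e3 else (3, None, 0)]
                ll = famcr.forward_loglik(
                    FamilyHistory("f", tuple(recs)), params, T,
                    noncapture_date=d)
                if np.isfinite(ll):
                    total += np.exp(ll)
    assert total == pytest.approx(1.0, abs=1e-10)
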