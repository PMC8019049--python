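import numpy as np
import pytest
from scipy import stats

import famcr
from famcr.matrices import build_e1, build_transition
from famcr.simulate import _sample_row, scenario, uniform_dates
from famcr.states import A02, AS1, AS2, D, N_ALIVE


def test_scenario_presets_encode_design():
    for name, p, kind in [("S1", 0.25, "constant"), ("S2", 0.25, "seasonal"),
                          ("S3", 0.7, "constant"), ("S4", 0.7, "seasonal")]:
        cfg = scenario(name)
        assert cfg.T == 15 and cfg.R == 80
        assert cfg.true_params.p[0] == p
        assert cfg.true_params.departure.kind == kind
        assert cfg.true_params.kappa == 0.0
    with pytest.raises(ValueError):
        scenario("S9")


def test_capture_dates_within_season(rng):
    cfg = scenario("S1")
    draws = np.array([famcr.sample_capture_date(cfg, rng) for _ in range(500)])
    assert draws.min() >= 80.0 and draws.max() <= 130.0
    big = uniform_dates()(rng, 10_000)
    assert big.mean() == pytest.approx(105.0, abs=1.0)
    point = famcr.ScenarioConfig(date_sampler=lambda r, n: np.full(n, 100.0))
    assert famcr.sample_capture_date(point, rng) == 100.0


def test_empirical_date_sampler(rng):
    obs = np.array([85.0, 90.0, 95.0])
    draws = famcr.empirical_dates(obs)(rng, 1000)
    assert set(np.unique(draws)) <= set(obs)


def test_dataset_size_and_first_capture(rng):
    cfg = scenario("S3")
    data = famcr.simulate_dataset(cfg, rng)
    assert len(data) == cfg.T * cfg.R == 1200
    assert all(h.records[0][2] != 0 for h in data.histories)
    assert all(h.records[-1][0] == cfg.T for h in data.histories)


def test_equal_state_allocation_exact_when_divisible():
    cfg = scenario("S3")
    cfg.R = 11
    cfg.T = 3
    from famcr.simulate import _initial_states
    states = _initial_states(cfg, np.random.default_rng(0))
    assert sorted(states) == list(range(N_ALIVE))


def test_fixed_seed_reproducible():
    cfg = scenario("S2")
    cfg.T, cfg.R = 5, 11
    a = famcr.simulate_dataset(cfg, 42)
    b = famcr.simulate_dataset(cfg, 42)
    assert a == b


def test_forced_departure_always_seen_alone(rng):
    cfg = scenario("S3")
    cfg.true_params = famcr.simulation_truth(
        p=1.0, departure=famcr.DepartureModel(kind="constant", alpha0=1.0))
    for _ in range(20):
        h = famcr.simulate_family(AS1, 1, cfg, rng)
        assert h.records[0][2] == 11


def test_no_observation_after_mother_death(rng):
    cfg = scenario("S1")
    cfg.true_params = famcr.simulation_truth(
        p=1.0, departure=famcr.DepartureModel(kind="constant", alpha0=0.5))
    # kill quickly to exercise the absorbing state
    cfg.true_params = cfg.true_params.with_values(
        {f"phi{i}": 0.3 for i in range(1, 12)})
    for _ in range(50):
        h = famcr.simulate_family(A02, 1, cfg, rng)
        events = [e for _, _, e in h.records]
        # with p=1 the only nonobservations come after death, which is final
        if 0 in events:
            k = events.index(0)
            assert all(e == 0 for e in events[k:])


def test_sample_row_matches_distribution(rng):
    row = np.array([0.2, 0.5, 0.3])
    draws = np.array([_sample_row(row, rng) for _ in range(20_000)])
    freq = np.bincount(draws, minlength=3) / draws.size
    np.testing.assert_allclose(freq, row, atol=0.02)


def test_empirical_transitions_match_psi(truth):
    """One-step state frequencies agree with the transition matrix."""
    rng = np.random.default_rng(99)
    Psi = build_transition(truth)
    n = 20_000
    for state in (A02, AS2):
        counts = np.zeros(12)
        cum = np.cumsum(Psi[state])
        draws = np.searchsorted(cum, rng.random(n), side="right")
        for d in draws:
            counts[min(d, 11)] += 1
        support = Psi[state] > 0
        chi = stats.chisquare(counts[support], n * Psi[state][support])
        assert chi.pvalue > 0.01


def test_empirical_event_frequencies_match_e1(rng):
    """AS2 capture classes follow {2a(1-a), (1-a)^2, a^2}."""
    cfg = scenario("S3")  # constant alpha = 0.5
    a = 0.5
    params = cfg.true_params
    E1 = build_e1(params, 100.0)
    n = 10_000
    cum = np.cumsum(E1[AS2])
    draws = np.searchsorted(cum, rng.random(n), side="right")
    counts = np.bincount(draws, minlength=12)
    expected = np.array([2 * a * (1 - a), (1 - a) ** 2, a ** 2])
    np.testing.assert_allclose(E1[AS2, 8:11], expected, atol=1e-12)
    chi = stats.chisquare(counts[8:11], n * expected)
    assert chi.pvalue > 0.01
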