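"""Generative simulation of family-unit encounter histories.

The simulator draws latent state trajectories from the annual transition
Psi and observations from the two-step observation process (observation
class from E1 at a randomly drawn capture date, then detection from E2),
mirroring the study design: T sampling occasions, R newly marked family
units per occasion spread in equal proportion over the 11 alive states,
first capture forced (the likelihood conditions on it).

Four scenario presets cross detection level (low p = 0.25, high p = 0.7)
with the departure model for two-year-olds (constant alpha = 0.5 versus
a seasonal logistic rising from 0.40 at day 80 to 0.80 at day 130):
S1 low/constant, S2 low/seasonal, S3 high/constant, S4 high/seasonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .data import Dataset, FamilyHistory
from .matrices import build_e1, build_transition
from .params import DepartureModel, ParameterSet, uniform_pi
from .states import D, N_ALIVE, index_to_event

DateSampler = Callable[[np.random.Generator, int], np.ndarray]


def uniform_dates(low: float = 80.0, high: float = 130.0) -> DateSampler:
    """Capture dates uniform over the spring field season."""
    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size)
    return sampler


def empirical_dates(observed: np.ndarray) -> DateSampler:
    """Resample capture dates from an observed day-of-year collection."""
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("need at least one observed date")
    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(observed, size=size, replace=True)
    return sampler


def simulation_truth(p: float = 0.25,
                     departure: DepartureModel | None = None) -> ParameterSet:
    """Generating parameters of the long-lived virtual species.

    Survival 0.9 for all independent stages; singleton/twin cub survival
    0.6/0.55, singleton/twin yearling survival 0.8/0.75; breeding
    probabilities (0.5, 0.7, 0.9, 0.8); singleton-litter probabilities
    (0.4, 0.5, 0.6, 0.7); kappa = 0 (first litter at age 6 or older);
    shared detection ``p``; equal initial proportions.
    """
    return ParameterSet(
        phi=np.full(11, 0.9),
        s=np.array([0.6, 0.55, 0.8, 0.75]),
        kappa=0.0,
        beta=np.array([0.5, 0.7, 0.9, 0.8]),
        gamma=np.array([0.4, 0.5, 0.6, 0.7]),
        p=np.full(11, p),
        pi=uniform_pi(),
        departure=departure if departure is not None else DepartureModel(),
    )


@dataclass
class ScenarioConfig:
    """Simulation design: occasions, marking effort, truth, observation."""

    T: int = 15
    R: int = 80
    true_params: ParameterSet = field(default_factory=simulation_truth)
    date_sampler: DateSampler = field(default_factory=uniform_dates)
    initial_distribution: str = "equal"  # or "pi": sample states from true pi
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("need at least T = 2 occasions")
        if self.R < 1:
            raise ValueError("need at least R = 1 new family per occasion")
        if self.initial_distribution not in ("equal", "pi"):
            raise ValueError("initial_distribution must be 'equal' or 'pi'")


SCENARIOS = ("S1", "S2", "S3", "S4")


def scenario(name: str) -> ScenarioConfig:
    """Preset S1-S4: (low|high detection) x (constant|seasonal departure)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    p = 0.25 if name in ("S1", "S2") else 0.7
    dep = DepartureModel(kind="constant", alpha0=0.5) if name in ("S1", "S3") \
        else DepartureModel(kind="seasonal")
    return ScenarioConfig(T=15, R=80, true_params=simulation_truth(p, dep),
                          name=name)


def sample_capture_date(cfg: ScenarioConfig, rng: np.random.Generator) -> float:
    """Draw one capture day-of-year from the configured date distribution."""
    return float(cfg.date_sampler(rng, 1)[0])


def _sample_row(row: np.ndarray, rng: np.random.Generator) -> int:
    # inverse-cdf draw; cheaper than rng.choice for many small rows
    idx = int(np.searchsorted(np.cumsum(row), rng.random(), side="right"))
    return min(idx, row.shape[0] - 1)


def simulate_family(initial_state: int, first_occasion: int,
                    cfg: ScenarioConfig, rng: np.random.Generator
                    ) -> FamilyHistory:
    """Simulate one family from its (forced) first capture to occasion T.

    The latent trajectory follows Psi(true_params); at each occasion an
    observation class is drawn from E1 at a fresh capture date and
    detection from the class's probability. The first occasion is a
    capture by construction and skips the detection draw. After the
    mother's death the family emits only nonobservations.
    """
    if not 0 <= initial_state < N_ALIVE:
        raise ValueError("initial state must be one of the 11 alive states")
    params = cfg.true_params
    Psi = build_transition(params)
    records = []
    state = initial_state
    for occ in range(first_occasion, cfg.T + 1):
        first = occ == first_occasion
        if not first:
            state = _sample_row(Psi[state], rng)
        if state == D:
            records.append((occ, None, 0))
            continue
        d = sample_capture_date(cfg, rng)
        cls = _sample_row(build_e1(params, d)[state], rng)
        if first:
            # conditioned on first capture: observation class drawn, no
            # detection draw; alive states never emit the class-12 column
            records.append((occ, d, index_to_event(cls)))
        elif cls < 11 and rng.random() < params.p[cls]:
            records.append((occ, d, index_to_event(cls)))
        else:
            records.append((occ, None, 0))
    return FamilyHistory(f"F{first_occasion:03d}x{initial_state:02d}", records)


def _initial_states(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """States of the R families newly marked at one occasion."""
    if cfg.initial_distribution == "pi":
        return rng.choice(N_ALIVE, size=cfg.R, p=cfg.true_params.pi)
    base, rem = divmod(cfg.R, N_ALIVE)
    counts = np.full(N_ALIVE, base, dtype=int)
    if rem:
        counts[rng.choice(N_ALIVE, size=rem, replace=False)] += 1
    return np.repeat(np.arange(N_ALIVE), counts)


def simulate_dataset(cfg: ScenarioConfig,
                     rng: np.random.Generator | int) -> Dataset:
    """Simulate a full study: R new families at each of the T occasions."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    histories = []
    for occ in range(1, cfg.T + 1):
        for j, state in enumerate(_initial_states(cfg, rng)):
            fam = simulate_family(int(state), occ, cfg, rng)
            histories.append(
                FamilyHistory(f"F{occ:03d}_{j:03d}", fam.records))
    return Dataset(tuple(histories), cfg.T)
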