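import numpy as np
import pytest

import famcr
from famcr.params import DepartureModel, ParameterSet


def random_parameters(rng: np.random.Generator,
                      kind: str = "constant") -> ParameterSet:
    """Random valid ParameterSet, away from the 0/1 boundaries."""
    dep = DepartureModel(kind=kind, alpha0=float(rng.uniform(0.1, 0.9)))
    return ParameterSet(
        phi=rng.uniform(0.2, 0.95, 11),
        s=rng.uniform(0.2, 0.9, 4),
        kappa=float(rng.uniform(0.0, 1.0)),
        beta=rng.uniform(0.1, 0.9, 4),
        gamma=rng.uniform(0.1, 0.9, 4),
        p=rng.uniform(0.1, 0.9, 11),
        pi=rng.dirichlet(np.ones(11)),
        departure=dep,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def truth():
    """Generating parameters of the scenario presets (constant departure)."""
    return famcr.simulation_truth()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by likelihood/fit smoke tests."""
    cfg = famcr.ScenarioConfig(T=8, R=22,
                               true_params=famcr.simulation_truth(p=0.7))
    return famcr.simulate_dataset(cfg, np.random.default_rng(11)), cfg
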