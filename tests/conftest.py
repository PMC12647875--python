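import numpy as np
import pandas as pd
import pytest

from lifespan_topology.synthetic import (
    PlantedTrajectorySpec,
    generate_metric_trajectories,
    generate_toy_network,
)


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    """Random symmetric weighted graph with distinct continuous weights."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < p
    w = rng.uniform(0.1, 1.0, iu[0].size) * present
    m[iu] = w
    m += m.T
    return m


@pytest.fixture(scope="session")
def toy_graphs() -> dict[str, np.ndarray]:
    return {
        "triangle": generate_toy_network("ring", 3),
        "p3": generate_toy_network("path", 3),
        "star": generate_toy_network("star", 5),
        "k4": generate_toy_network("complete", 4),
        "k5": generate_toy_network("complete", 5),
        "two_cliques": generate_toy_network("two_cliques", 10),
    }


@pytest.fixture(scope="session")
def random_graphs() -> list[np.ndarray]:
    rng = np.random.default_rng(42)
    return [
        random_graph(rng, int(rng.integers(4, 13)), p=0.5) for _ in range(50)
    ]


@pytest.fixture(scope="session")
def planted_table_noiseless() -> tuple[pd.DataFrame, dict]:
    spec = PlantedTrajectorySpec(noise_sd=0.0, n_per_age=2, seed=7)
    return generate_metric_trajectories(spec)


@pytest.fixture(scope="session")
def planted_table_noisy() -> tuple[pd.DataFrame, dict]:
    spec = PlantedTrajectorySpec(noise_sd=0.3, n_per_age=20, seed=1)
    return generate_metric_trajectories(spec)
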