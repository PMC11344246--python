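import numpy as np
import pytest

from targetforest.pcsf import PCSFInstance
from targetforest.synthetic import simulate_all


def random_pcsf_instance(rng, max_nodes=8, max_edges=12, edge_p=0.4,
                         omegas=(0.25, 0.5)):
    """Random small instance: prizes/costs ~ U(0,1), Erdos-Renyi edges."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    while True:
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < edge_p:
                    edges.append((names[i], names[j], float(rng.uniform(0, 1))))
        if len(edges) <= max_edges:
            break
    prizes = {v: float(rng.uniform(0, 1)) for v in names}
    omega = float(rng.choice(omegas))
    return PCSFInstance(prizes=prizes, edges=edges, omega=omega)


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down synthetic study for fast pipeline-level tests."""
    return simulate_all(
        seed=7, n_genes=80, n_modules=4, n_differential=2, module_size=6,
        n_case=30, n_control=30, n_patients=30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
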