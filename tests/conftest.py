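import numpy as np
import pytest

import connectome_backbone as cb


def random_graph(rng: np.random.Generator, n: int, p: float | None = None) -> cb.BackboneGraph:
    """Erdos-Renyi-style random graph for oracle comparisons."""
    if p is None:
        p = rng.uniform(0.2, 0.9)
    iu = np.triu_indices(n, k=1)
    keep = rng.random(iu[0].size) < p
    return cb.BackboneGraph.from_edges(n, zip(iu[0][keep], iu[1][keep]))


def path_graph(n: int) -> cb.BackboneGraph:
    return cb.BackboneGraph.from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n: int) -> cb.BackboneGraph:
    """Hub = node 0, n-1 leaves."""
    return cb.BackboneGraph.from_edges(n, [(0, i) for i in range(1, n)])


def complete_graph(n: int) -> cb.BackboneGraph:
    return cb.BackboneGraph.from_edges(
        n, [(i, j) for i in range(n) for j in range(i + 1, n)]
    )


def cycle_graph(n: int) -> cb.BackboneGraph:
    return cb.BackboneGraph.from_edges(n, [(i, (i + 1) % n) for i in range(n)])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by the slower end-to-end tests."""
    cohort, backbone, modules = cb.sample_cohort(cb.CohortConfig(seed=1))
    return cohort, backbone, modules


@pytest.fixture(scope="session")
def default_snr(default_cohort):
    cohort, _, _ = default_cohort
    return cb.compute_snr(cohort, "1yr")
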