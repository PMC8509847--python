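import sys
from pathlib import Path

import numpy as np
import pytest

# make the brute-force oracle importable regardless of invocation style
sys.path.insert(0, str(Path(__file__).parent))

import fbandnet as fb


@pytest.fixture(scope="session")
def small_cohort():
    """A compact paired cohort with one planted band-1 effect."""
    spec = fb.CohortSpec(
        n_subjects=6,
        n_regions=20,
        n_volumes=128,
        base_connectivity=fb.ModularTemplate(n_modules=4, within_r=0.5, between_r=0.1),
        effect_edges=[fb.EffectEdge(0, 4, 1, -0.3)],
        seed=11,
    )
    return fb.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng: np.random.Generator, n: int, p: float = None) -> "fb.Graph":
    """Random simple undirected graph with at least one edge."""
    p = p if p is not None else rng.uniform(0.2, 0.8)
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, k=1)
        adj = adj | adj.T
        if adj.any():
            return fb.Graph(adjacency=adj)
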