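from __future__ import annotations

import random

import pytest

from mnalign.core import (
    AlignmentParams,
    Network,
    NetworkCollection,
    SimilarityMatrix,
    _canon,
)
from mnalign.synthetic import worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """The two-network worked example: (networks, raw similarity)."""
    return worked_example_fixture()


@pytest.fixture
def pairwise_params():
    """Pairwise-mode parameters used throughout the worked example."""
    return AlignmentParams(tau=50.0, beta=0.1, rho=0.6, omega=2.5)


def random_instance(
    rng: random.Random,
    *,
    k: int = 2,
    max_n: int = 15,
    p_edge: float = 0.3,
    p_sim: float = 0.3,
) -> tuple[NetworkCollection, SimilarityMatrix]:
    """A small random multi-network instance for oracle comparisons."""
    networks = []
    for i in range(k):
        n = rng.randint(2, max_n)
        vs = [f"n{i}v{j}" for j in range(n)]
        edges = {
            _canon(a, b)
            for a in vs
            for b in vs
            if a < b and rng.random() < p_edge
        }
        networks.append(Network(f"net{i}", frozenset(vs), frozenset(edges)))
    nets = NetworkCollection(networks)
    entries = {}
    vs_by_net = [sorted(g.vertices) for g in networks]
    for i in range(k):
        for j in range(i + 1, k):
            for a in vs_by_net[i]:
                for b in vs_by_net[j]:
                    if rng.random() < p_sim:
                        entries[_canon(a, b)] = rng.uniform(0.1, 100.0)
    return nets, SimilarityMatrix(entries)


def random_alignment(
    rng: random.Random, nets: NetworkCollection
) -> "Alignment":
    """A random valid alignment covering a random subset of proteins."""
    from mnalign.core import Alignment

    proteins = sorted(nets.vertices)
    rng.shuffle(proteins)
    sets = []
    idx = 0
    while idx + 1 < len(proteins):
        size = rng.randint(2, 4)
        group = proteins[idx : idx + size]
        if len(group) >= 2:
            sets.append(frozenset(group))
        idx += size + rng.randint(0, 2)  # leave some proteins uncovered
    return Alignment(sets)
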