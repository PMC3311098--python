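"""Test inputs: a small two-network worked example and a planted-ortholog
simulator.

The worked example is a pair of toy networks whose raw similarity scores
were reconstructed from four printed score identities (the sum 85 of the
topology-aware alignment, the Hungarian optimum 95, the 80 of the
no-preprocessing alignment, and one explicitly zero pair); the builder
re-checks all four identities at run time so any transcription error
fails fast.

The simulator plants ground-truth ortholog groups by copying an
Erdős–Rényi ancestor graph into k networks with independent edge
deletions, giving true cross-network pairs a strong similarity signal and
sprinkling weak spurious scores.  It emulates what the aligner assumes —
sparse graphs with a sparse block-structured similarity matrix — not
realistic PPI degree distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    AnnotationMap,
    InputFormatError,
    Network,
    NetworkCollection,
    SimilarityMatrix,
    _canon,
)


def worked_example_fixture() -> tuple[NetworkCollection, SimilarityMatrix]:
    """The two-network worked example.

    Network A is the path A1-A2-A3; network B is the star B1-B2, B2-B3,
    B2-B4.  Raw scores: sim(A1,B1)=20, sim(A2,B2)=50, sim(A2,B3)=60,
    sim(A3,B4)=15, everything else 0.
    """
    a1b1, a2b2, a2b3, a3b4 = 20.0, 50.0, 60.0, 15.0
    # self-check against the printed score identities the values were
    # reconstructed from
    assert a1b1 + a2b2 + a3b4 == 85.0  # topology-aware alignment sum
    assert a1b1 + a2b3 + a3b4 == 95.0  # Hungarian optimum
    assert a1b1 + a2b3 + 0.0 == 80.0  # no-preprocessing alignment sum
    # sim(A3, B2) = 0: it is simply not an entry below

    net_a = Network(
        "A",
        frozenset({"A1", "A2", "A3"}),
        frozenset({("A1", "A2"), ("A2", "A3")}),
    )
    net_b = Network(
        "B",
        frozenset({"B1", "B2", "B3", "B4"}),
        frozenset({("B1", "B2"), ("B2", "B3"), ("B2", "B4")}),
    )
    nets = NetworkCollection([net_a, net_b])
    sim = SimilarityMatrix(
        {
            ("A1", "B1"): a1b1,
            ("A2", "B2"): a2b2,
            ("A2", "B3"): a2b3,
            ("A3", "B4"): a3b4,
        }
    )
    return nets, sim


@dataclass
class PlantedTruth:
    """Ground-truth ortholog groups with the generator settings."""

    groups: list[frozenset[str]]
    k: int
    n0: int
    p_edge: float
    p_del: float
    sim_signal: float
    sim_noise: tuple[float, float]
    seed: int

    def true_pairs(self) -> set[tuple[str, str]]:
        """All unordered cross-network pairs inside the planted groups."""
        pairs: set[tuple[str, str]] = set()
        for g in self.groups:
            members = sorted(g)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(_canon(a, b))
        return pairs


def generate_planted(
    k: int = 2,
    n0: int = 50,
    p_edge: float = 0.1,
    p_del: float = 0.1,
    sim_signal: float = 100.0,
    sim_noise: tuple[float, float] = (0.01, 30.0),
    seed: int = 0,
    *,
    sim_jitter: float = 0.0,
) -> tuple[NetworkCollection, SimilarityMatrix, PlantedTruth]:
    """Duplication-and-divergence instance with known ortholog groups.

    An ancestor graph G(n0, p_edge) is copied into k networks; each copy
    independently loses every edge with probability p_del (all vertices are
    kept, so isolated proteins can occur).  Copies of the same ancestor
    protein get similarity sim_signal, optionally jittered by a uniform
    factor in [1 - sim_jitter, 1 + sim_jitter]; every other cross-network
    pair receives a spurious score uniform on (0, sim_noise[1]] with
    probability sim_noise[0].  Deterministic for a fixed seed.
    """
    if k < 2 or n0 < 5:
        raise InputFormatError("need k >= 2 networks and n0 >= 5 proteins")
    if not (0 <= p_edge <= 1 and 0 <= p_del <= 1 and 0 <= sim_noise[0] <= 1):
        raise InputFormatError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = nx.gnp_random_graph(n0, p_edge, seed=int(rng.integers(2**31)))

    def pid(net: int, anc: int) -> str:
        return f"n{net + 1}p{anc:03d}"

    networks = []
    for i in range(k):
        vertices = frozenset(pid(i, j) for j in range(n0))
        edges = frozenset(
            _canon(pid(i, a), pid(i, b))
            for a, b in ancestor.edges
            if rng.random() >= p_del
        )
        networks.append(Network(f"net{i + 1}", vertices, edges))
    nets = NetworkCollection(networks)

    entries: dict[tuple[str, str], float] = {}
    groups = [
        frozenset(pid(i, j) for i in range(k)) for j in range(n0)
    ]
    for j in range(n0):
        for i1 in range(k):
            for i2 in range(i1 + 1, k):
                s = sim_signal
                if sim_jitter:
                    s *= 1 + sim_jitter * (2 * rng.random() - 1)
                if s > 0:
                    entries[_canon(pid(i1, j), pid(i2, j))] = s
    noise_rate, noise_max = sim_noise
    if noise_rate > 0 and noise_max > 0:
        for j1 in range(n0):
            for j2 in range(n0):
                if j1 == j2:
                    continue
                for i1 in range(k):
                    for i2 in range(i1 + 1, k):
                        if rng.random() < noise_rate:
                            key = _canon(pid(i1, j1), pid(i2, j2))
                            entries.setdefault(
                                key, float(rng.uniform(0, noise_max)) or noise_max
                            )
    if not entries:
        raise InputFormatError(
            "generator parameters produced an empty similarity matrix"
        )
    sim = SimilarityMatrix(entries)
    truth = PlantedTruth(
        groups, k, n0, p_edge, p_del, sim_signal, sim_noise, seed
    )
    return nets, sim, truth


def generate_annotations(
    truth: PlantedTruth,
    term_per_group: bool = True,
    background_terms: int = 0,
    seed: int = 0,
) -> AnnotationMap:
    """Synthetic GO-style annotations for a planted instance.

    With ``term_per_group`` every ortholog group gets its own term on all
    of its members; ``background_terms`` extra terms are sprinkled over
    random proteins (5 each) as noise.
    """
    rng = np.random.default_rng(seed)
    ann: AnnotationMap = {}
    if term_per_group:
        for g_idx, group in enumerate(truth.groups):
            term = f"GO:{g_idx:07d}"
            for v in group:
                ann.setdefault(v, set()).add(term)
    if background_terms:
        proteins = sorted(
            {v for g in truth.groups for v in g}
        )
        for t in range(background_terms):
            term = f"GO:BG{t:05d}"
            for v in rng.choice(proteins, size=min(5, len(proteins)), replace=False):
                ann.setdefault(str(v), set()).add(term)
    return ann


def pair_recovery(
    alignment_pairs: set[tuple[str, str]],
    truth: PlantedTruth,
) -> tuple[float, float, float]:
    """(precision, recall, F1) of aligned cross-network pairs against the
    planted groups."""
    true_pairs = truth.true_pairs()
    if not alignment_pairs:
        return 0.0, 0.0, 0.0
    tp = len(alignment_pairs & true_pairs)
    precision = tp / len(alignment_pairs)
    recall = tp / len(true_pairs) if true_pairs else 0.0
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def aligned_cross_pairs(
    alignment, nets: NetworkCollection
) -> set[tuple[str, str]]:
    """All unordered cross-network pairs co-located in a match-set."""
    pairs: set[tuple[str, str]] = set()
    for ms in alignment:
        members = sorted(ms.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if nets.net_of(a) != nets.net_of(b):
                    pairs.add(_canon(a, b))
    return pairs
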