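"""Stage 1: grouping proteins by similarity with agglomerative clustering.

The aligner needs groups of *mutually* similar proteins from which to draw
seed pairs.  Two criterion functions are supported:

* I1 — sum over clusters of (within-cluster pair-similarity sum) / size;
  this resembles the average similarity of each cluster and tends to give
  the highest downstream match-set similarity.
* I2 — plain sum over clusters of the within-cluster pair-similarity sum.

Clustering is greedy agglomerative: starting from singletons, repeatedly
merge the cluster pair with the greatest criterion gain (gains may turn
negative near the end) until the target count is reached.  Merges are
restricted to cluster pairs connected by at least one nonzero similarity
entry whenever such a pair exists.  The default cluster count is
n_sim / k — roughly one cluster per ortholog group when every network
contributes one member — where n_sim counts proteins that have at least
one nonzero similarity entry (all others are excluded before clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import (
    InputFormatError,
    NetworkCollection,
    SimilarityMatrix,
)


@dataclass
class ClusterSet:
    """A partition of the nonzero-similarity proteins."""

    clusters: list[frozenset[str]]
    criterion: str
    criterion_value: float = 0.0

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class MergeStep:
    """One agglomerative merge, recorded for auditing."""

    merged: tuple[frozenset[str], frozenset[str]]
    gain: float
    connected: bool


def _within_sum(cluster: frozenset[str], sim: SimilarityMatrix) -> float:
    members = sorted(cluster)
    total = 0.0
    for i, v in enumerate(members):
        partners = sim.partners(v)
        for u in members[i + 1 :]:
            total += partners.get(u, 0.0)
    return total


def criterion_value(
    clusters: ClusterSet | list[frozenset[str]],
    sim: SimilarityMatrix,
    which: str,
) -> float:
    """Evaluate I1 or I2 on a partition (unordered distinct pairs;
    within-network pairs contribute 0 through the similarity matrix)."""
    if which not in ("i1", "i2"):
        raise InputFormatError("criterion must be 'i1' or 'i2'")
    cluster_list = clusters.clusters if isinstance(clusters, ClusterSet) else clusters
    total = 0.0
    for c in cluster_list:
        if not c:
            raise InputFormatError("empty cluster")
        w = _within_sum(c, sim)
        total += w / len(c) if which == "i1" else w
    return total


def target_cluster_count(
    nets: NetworkCollection, sim: SimilarityMatrix
) -> int:
    """Default number of clusters: max(1, floor(n_sim / k))."""
    n_sim = len(sim.proteins())
    if n_sim == 0:
        raise InputFormatError("no alignable proteins (similarity matrix empty)")
    return max(1, n_sim // nets.k)


def _gain(
    which: str, wi: float, ni: int, wj: float, nj: int, cross: float
) -> float:
    if which == "i2":
        return cross
    return (wi + wj + cross) / (ni + nj) - wi / ni - wj / nj


def agglomerative_cluster(
    sim: SimilarityMatrix,
    m: int,
    which: str = "i1",
    *,
    trace: list[MergeStep] | None = None,
) -> ClusterSet:
    """Greedy agglomerative clustering of the nonzero-similarity proteins
    into ``m`` clusters under criterion ``which``.

    Each step merges the connected cluster pair of maximal criterion gain
    (ties broken on the lexicographically smallest cluster-representative
    pair, a representative being a cluster's smallest member); when no
    connected pair remains, the two lexicographically smallest clusters are
    merged.  Pass ``trace`` to record every merge for auditing.
    """
    if which not in ("i1", "i2"):
        raise InputFormatError("criterion must be 'i1' or 'i2'")
    if m < 1:
        raise InputFormatError("cluster count must be >= 1")
    proteins = sorted(sim.proteins())
    if not proteins:
        raise InputFormatError("no alignable proteins (similarity matrix empty)")
    if m > len(proteins):
        warnings.warn(
            f"requested {m} clusters for {len(proteins)} proteins; "
            "returning all singletons",
            stacklevel=2,
        )
        m = len(proteins)

    # cluster id = lexicographically smallest member
    members: dict[str, frozenset[str]] = {v: frozenset([v]) for v in proteins}
    within: dict[str, float] = {v: 0.0 for v in proteins}
    rep: dict[str, str] = {v: v for v in proteins}  # protein -> cluster id
    cross: dict[tuple[str, str], float] = {}
    for a, b, s in sim.items():
        key = (a, b)  # items() is canonically ordered; singletons share ids
        cross[key] = cross.get(key, 0.0) + s

    while len(members) > m:
        best = None
        if cross:
            for (ci, cj), w in cross.items():
                g = _gain(
                    which,
                    within[ci],
                    len(members[ci]),
                    within[cj],
                    len(members[cj]),
                    w,
                )
                cand = (-g, ci, cj)
                if best is None or cand < best:
                    best = cand
            neg_g, ci, cj = best
            gain, connected = -neg_g, True
        else:
            ids = sorted(members)
            ci, cj = ids[0], ids[1]
            gain, connected = (
                _gain(
                    which,
                    within[ci],
                    len(members[ci]),
                    within[cj],
                    len(members[cj]),
                    0.0,
                ),
                False,
            )
        if trace is not None:
            trace.append(MergeStep((members[ci], members[cj]), gain, connected))

        # merge cj into ci (ci < cj by construction)
        w_cross = cross.pop((ci, cj), 0.0)
        within[ci] += within.pop(cj) + w_cross
        members[ci] = members[ci] | members.pop(cj)
        for v in members[ci]:
            rep[v] = ci
        # re-route cj's cross links to ci
        for key in [k for k in cross if cj in k]:
            other = key[0] if key[1] == cj else key[1]
            w = cross.pop(key)
            new_key = (ci, other) if ci < other else (other, ci)
            cross[new_key] = cross.get(new_key, 0.0) + w

    clusters = sorted(members.values(), key=lambda c: sorted(c))
    cs = ClusterSet(clusters, which)
    cs.criterion_value = criterion_value(cs, sim, which)
    return cs
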