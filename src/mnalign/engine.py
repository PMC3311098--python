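"""Stages 2-4 of the aligner: seeds, seed expansion, remaining proteins.

The aligner treats topology conservation and sequence similarity in
sequence rather than jointly: clusters of mutually similar proteins supply
*seed* pairs (stage 2), seeds are expanded outwards along network edges
with a max-priority queue so that each successful expansion conserves
edges (stage 3), and leftover unaligned proteins are paired purely by
similarity (stage 4).  A single merge criterion governs every union of two
match-sets; its three parameters (beta, rho, omega) bound how large,
similarity-diluted and single-species a match-set may become.

All pipeline *decisions* (clustering, the seed threshold tau, queue
priorities and the merge criterion) use the decision matrix — the
preprocessed scores when preprocessing is enabled — while reported metrics
always use the raw scores (see :mod:`mnalign.evaluation`).
"""

from __future__ import annotations

import heapq
import itertools
import time
from dataclasses import dataclass, field

from .clustering import ClusterSet, agglomerative_cluster, target_cluster_count
from .core import (
    Alignment,
    AlignmentParams,
    InputFormatError,
    NetworkCollection,
    SimilarityMatrix,
)
from .similarity import preprocess_similarity

SeedSet = set[tuple[str, str]]


def generate_seeds(
    clusters: ClusterSet,
    nets: NetworkCollection,
    sim: SimilarityMatrix,
    tau: float,
) -> SeedSet:
    """All within-cluster, cross-network pairs with decision score >= tau.

    The comparison is inclusive, so tau = 0 yields every cross-network pair
    inside each cluster, including zero-score ones.  Seeds are canonically
    ordered tuples; within-network pairs are never seeds.
    """
    if tau < 0:
        raise InputFormatError("tau must be >= 0")
    seeds: SeedSet = set()
    for cluster in clusters:
        for vx, vy in itertools.combinations(sorted(cluster), 2):
            if nets.net_of(vx) == nets.net_of(vy):
                continue
            if sim.get(vx, vy) >= tau:
                seeds.add((vx, vy))
    return seeds


@dataclass
class MergeCounters:
    attempts: int = 0
    accepts: int = 0
    rejects_size: int = 0
    rejects_similarity: int = 0
    zero_sim_singleton_merges: int = 0


class AlignmentState:
    """Mutable state of stages 3-4.

    Every protein starts in its own singleton match-set with ``ali`` false;
    ``ali`` becomes true only when the protein is one of the two endpoints
    of a successful merge, and N(v) — the unaligned neighbors of v — is
    derived from the ``ali`` flags on demand.
    """

    def __init__(self, nets: NetworkCollection, sim_decision: SimilarityMatrix):
        self.nets = nets
        self.sim = sim_decision
        self.match_set: dict[str, set[str]] = {
            v: {v} for v in nets.vertices
        }
        self.ali: dict[str, bool] = {v: False for v in nets.vertices}
        self.counters = MergeCounters()
        self._pq: list[tuple[float, int, str, str]] = []
        self._push_counter = 0
        self.merge_log: list[tuple[str, str]] = []

    # -- queue -----------------------------------------------------------

    def push(self, vx: str, vy: str) -> None:
        """Push a candidate pair keyed by its decision score; among equal
        priorities, later pushes pop first (lex-LIFO tie-break)."""
        self._push_counter += 1
        heapq.heappush(
            self._pq,
            (-self.sim.get(vx, vy), -self._push_counter, vx, vy),
        )

    def pop(self) -> tuple[str, str] | None:
        if not self._pq:
            return None
        _, _, vx, vy = heapq.heappop(self._pq)
        return vx, vy

    # -- derived views ---------------------------------------------------

    def unaligned_neighbors(self, v: str) -> list[str]:
        """N(v): neighbors of v that were never part of a successful merge."""
        return sorted(u for u in self.nets.neighbors(v) if not self.ali[u])

    def net_span(self, members: set[str]) -> set[str]:
        return {self.nets.net_of(v) for v in members}

    def to_alignment(self) -> Alignment:
        """Final alignment: the distinct match-sets with >= 2 members."""
        seen: set[int] = set()
        sets = []
        for s in self.match_set.values():
            if id(s) in seen or len(s) < 2:
                continue
            seen.add(id(s))
            sets.append(frozenset(s))
        return Alignment(sets)


def merge_criterion(
    vi: str,
    vj: str,
    state: AlignmentState,
    params: AlignmentParams,
    *,
    allow_zero_sim_singletons: bool = False,
) -> bool:
    """Decide whether to merge S(vi) and S(vj); merge and return True on
    acceptance.

    Gates, in order: (a) the union may hold at most omega proteins per
    network it spans; (b) singleton-singleton pairs merge unconditionally
    during seed expansion when ``allow_zero_sim_singletons`` is set;
    (c) otherwise the union must contain a positive score (maxSim > 0) and
    the number of cross-set pairs scoring above maxSim * beta, boosted by
    the network-expansion ratio, must reach |S(vi)| * |S(vj)| * rho.
    """
    si = state.match_set[vi]
    sj = state.match_set[vj]
    if si is sj:
        return False
    state.counters.attempts += 1
    union_nets = state.net_span(si) | state.net_span(sj)
    if len(si) + len(sj) > params.omega * len(union_nets):
        state.counters.rejects_size += 1
        return False

    def do_merge() -> bool:
        merged = si | sj
        for v in merged:
            state.match_set[v] = merged
        state.ali[vi] = True
        state.ali[vj] = True
        state.counters.accepts += 1
        state.merge_log.append((vi, vj))
        return True

    if (
        allow_zero_sim_singletons
        and params.merge_zero_sim_singletons
        and len(si) == 1
        and len(sj) == 1
    ):
        if state.sim.get(vi, vj) <= 0:
            state.counters.zero_sim_singleton_merges += 1
        return do_merge()

    union = sorted(si | sj)
    max_sim = 0.0
    for a, b in itertools.combinations(union, 2):
        s = state.sim.get(a, b)
        if s > max_sim:
            max_sim = s
    if max_sim <= 0:
        state.counters.rejects_similarity += 1
        return False
    threshold = max_sim * params.beta
    count = sum(
        1 for x in si for y in sj if state.sim.get(x, y) > threshold
    )
    expand_ratio = len(union_nets) / max(
        len(state.net_span(si)), len(state.net_span(sj))
    )
    if count * expand_ratio >= len(si) * len(sj) * params.rho:
        return do_merge()
    state.counters.rejects_similarity += 1
    return False


def expand_seeds(
    seeds: SeedSet, state: AlignmentState, params: AlignmentParams
) -> None:
    """Stage 3: merge seed pairs, then grow match-sets along edges.

    Phase 1 pushes every seed keyed by its decision score and applies the
    merge criterion to each in descending order (the boolean result is not
    consulted).  Phase 2 seeds the queue with the cross-network
    unaligned-neighbor pairs of every multi-member match-set, then pops:
    each successful merge of (vi, vj) pushes N(vi) x N(vj).  Entries are
    validated at pop time — pairs already co-located, or whose endpoints
    have since been aligned, are skipped as stale.
    """
    # phase 1: seed unions
    for vx, vy in sorted(seeds):
        state.push(vx, vy)
    while (pair := state.pop()) is not None:
        vx, vy = pair
        merge_criterion(
            vx, vy, state, params, allow_zero_sim_singletons=True
        )

    # phase 2: expansion along edges
    seen: set[int] = set()
    for v in sorted(state.match_set):
        s = state.match_set[v]
        if id(s) in seen or len(s) < 2:
            continue
        seen.add(id(s))
        for vi, vj in itertools.combinations(sorted(s), 2):
            if state.nets.net_of(vi) == state.nets.net_of(vj):
                continue
            _push_neighbor_pairs(vi, vj, state)
    while (pair := state.pop()) is not None:
        vi, vj = pair
        if state.match_set[vi] is state.match_set[vj]:
            continue
        if state.ali[vi] or state.ali[vj]:
            continue  # stale: no longer an unaligned-neighbor pair
        if merge_criterion(
            vi, vj, state, params, allow_zero_sim_singletons=True
        ):
            _push_neighbor_pairs(vi, vj, state)


def _push_neighbor_pairs(vi: str, vj: str, state: AlignmentState) -> None:
    """Push all cross-network pairs from N(vi) x N(vj), in lexicographic
    order (so LIFO popping prefers the lexicographically last among ties)."""
    ni = state.unaligned_neighbors(vi)
    nj = state.unaligned_neighbors(vj)
    for vx in ni:
        for vy in nj:
            if state.nets.net_of(vx) != state.nets.net_of(vy):
                state.push(vx, vy)


def align_remaining(
    state: AlignmentState, params: AlignmentParams
) -> None:
    """Stage 4: pair leftover proteins purely by similarity.

    Candidate pairs are those whose endpoints were both unaligned when the
    stage starts and whose decision score is positive; they are processed
    in descending score order and each one is offered to the merge
    criterion, so chains of candidates can grow multi-network match-sets.
    """
    candidates = [
        (s, a, b)
        for a, b, s in state.sim.items()
        if not state.ali[a] and not state.ali[b]
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, a, b in candidates:
        if state.match_set[a] is state.match_set[b]:
            continue
        merge_criterion(a, b, state, params)


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    params: AlignmentParams
    preprocess: bool
    n_proteins: int
    n_networks: int
    n_clusters: int = 0
    n_seeds: int = 0
    counters: MergeCounters = field(default_factory=MergeCounters)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    clustering_runs: int = 0


def run_pipeline(
    nets: NetworkCollection,
    sim_raw: SimilarityMatrix,
    params: AlignmentParams | None = None,
) -> tuple[Alignment, RunReport]:
    """Full pipeline: preprocess -> cluster -> seed -> expand -> remainder.

    Returns the final alignment (match-sets of >= 2 proteins) and a report
    with stage timings and merge counters.  Deterministic for fixed params.
    """
    params = params or AlignmentParams()
    if nets.k < 2:
        raise InputFormatError("alignment needs at least 2 networks")
    report = RunReport(
        params=params,
        preprocess=params.preprocess,
        n_proteins=nets.n,
        n_networks=nets.k,
    )

    t0 = time.perf_counter()
    sim_dec = preprocess_similarity(nets, sim_raw) if params.preprocess else sim_raw
    report.stage_seconds["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    m = params.cluster_count_override or target_cluster_count(nets, sim_dec)
    clusters = agglomerative_cluster(sim_dec, m, params.criterion)
    report.clustering_runs += 1
    report.n_clusters = len(clusters)
    report.stage_seconds["clustering"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seeds = generate_seeds(clusters, nets, sim_dec, params.tau)
    report.n_seeds = len(seeds)
    report.stage_seconds["seeding"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    state = AlignmentState(nets, sim_dec)
    expand_seeds(seeds, state, params)
    report.stage_seconds["expansion"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    align_remaining(state, params)
    report.stage_seconds["remaining"] = time.perf_counter() - t0

    report.counters = state.counters
    return state.to_alignment(), report
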