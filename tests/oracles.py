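"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (full enumeration, no incremental
bookkeeping) so it can serve as an oracle for the optimized code paths.
"""

from __future__ import annotations

import itertools
import math

from mnalign.core import Alignment, NetworkCollection, SimilarityMatrix


def conserved_edges_bruteforce(
    alignment: Alignment, nets: NetworkCollection
) -> int:
    """O(|E|^2) pairwise scan over all edges."""
    edges = list(nets.edges())
    count = 0
    for net_i, a, b in edges:
        ia, ib = alignment.index_of(a), alignment.index_of(b)
        if ia is None or ib is None:
            continue
        if ia == ib:
            count += 1
            continue
        ok = False
        for net_j, x, y in edges:
            if net_j == net_i:
                continue
            ix, iy = alignment.index_of(x), alignment.index_of(y)
            if {ix, iy} == {ia, ib}:
                ok = True
                break
        count += ok
    return count


def strictly_conserved_bruteforce(
    alignment: Alignment, nets: NetworkCollection, sim: SimilarityMatrix
) -> int:
    edges = list(nets.edges())
    count = 0
    for net_i, a, b in edges:
        ia, ib = alignment.index_of(a), alignment.index_of(b)
        if ia is None or ib is None:
            continue
        ok = False
        for net_j, x, y in edges:
            if net_j == net_i:
                continue
            for xx, yy in ((x, y), (y, x)):
                if (
                    alignment.index_of(xx) == ia
                    and alignment.index_of(yy) == ib
                    and sim.get(a, xx) > 0
                    and sim.get(b, yy) > 0
                ):
                    ok = True
            if ok:
                break
        count += ok
    return count


def hypergeom_sum(N: int, M: int, n: int, m: int) -> float:
    """Direct combinatorial upper-tail sum."""
    total = sum(
        math.comb(M, i) * math.comb(N - M, n - i)
        for i in range(m, min(n, M) + 1)
        if n - i <= N - M
    )
    return total / math.comb(N, n)


def hungarian_bruteforce(
    nets: NetworkCollection, sim: SimilarityMatrix
) -> float:
    """Maximum one-to-one assignment total score by full enumeration."""
    va = sorted(nets.networks[0].vertices)
    vb = sorted(nets.networks[1].vertices)
    if len(va) > len(vb):
        va, vb = vb, va
    best = 0.0
    for perm in itertools.permutations(vb, len(va)):
        best = max(best, sum(sim.get(a, b) for a, b in zip(va, perm)))
    return best


def greedy_extra_bruteforce(
    va: str, vb: str, nets: NetworkCollection, sim: SimilarityMatrix
) -> float:
    """Step-by-step greedy neighbor matching, re-scanning every remaining
    pair at each step (same rule, independent mechanics)."""
    avail_a = set(nets.neighbors(va))
    avail_b = set(nets.neighbors(vb))
    extra = 0.0
    while avail_a and avail_b:
        best = None
        for x in avail_a:
            for y in avail_b:
                s = sim.get(x, y)
                key = (-s, min(x, y), max(x, y))
                if best is None or key < best[0]:
                    best = (key, x, y, s)
        _, x, y, s = best
        if s <= 0:
            break
        extra += s
        avail_a.discard(x)
        avail_b.discard(y)
    return extra


def average_similarity_bruteforce(
    alignment: Alignment, sim: SimilarityMatrix
) -> float:
    num = den = 0.0
    for ms in alignment:
        members = sorted(ms.members)
        pair_sum = sum(
            sim.get(a, b) for a, b in itertools.combinations(members, 2)
        )
        num += len(members) * pair_sum / math.comb(len(members), 2)
        den += len(members)
    return num / den
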