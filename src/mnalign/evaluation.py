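"""Alignment-quality metrics and the Hungarian max-similarity baseline.

All metrics are computed on the *raw* similarity matrix, never the
preprocessed one: preprocessing exists to steer the aligner's decisions,
while reported similarity should reflect actual sequence similarity.

An edge (vx, vy) of network i is *conserved* by an alignment when
(1) some edge (vx', vy') of a different network j has S(vx) = S(vx') and
S(vy) = S(vy'), or (2) vx and vy are in the same match-set.  A *strictly*
conserved edge additionally requires a condition-(1) witness with
sim(vx, vx') > 0 and sim(vy, vy') > 0.  The *conserved edge rate* divides
the conserved count by the number of edges whose endpoints are both
covered by the alignment.

Functional coherence is scored with the upper-tail hypergeometric
p-value of each match-set against each GO term annotating at least one of
its members, with the background N being the total protein count of all
networks (unannotated proteins count toward N - M).  A term is *enriched*
when some match-set reaches p < 1e-4; no multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .core import (
    Alignment,
    AnnotationMap,
    InputFormatError,
    MatchSet,
    NetworkCollection,
    SimilarityMatrix,
)

ENRICHMENT_ALPHA = 1e-4


def match_set_similarity(S: MatchSet, sim_raw: SimilarityMatrix) -> float:
    """sim(S): mean raw similarity over the C(|S|, 2) unordered pairs."""
    members = sorted(S.members)
    if len(members) < 2:
        raise InputFormatError("match-set similarity needs >= 2 members")
    total = 0.0
    for i, a in enumerate(members):
        partners = sim_raw.partners(a)
        for b in members[i + 1 :]:
            total += partners.get(b, 0.0)
    return total / math.comb(len(members), 2)


def average_similarity(
    alignment: Alignment, sim_raw: SimilarityMatrix
) -> float:
    """Size-weighted mean of sim(S_i) over the match-sets."""
    if len(alignment) == 0:
        raise InputFormatError("average similarity of an empty alignment")
    num = sum(
        len(ms) * match_set_similarity(ms, sim_raw) for ms in alignment
    )
    den = sum(len(ms) for ms in alignment)
    return num / den


def _edge_keys(nets: NetworkCollection, alignment: Alignment):
    """Per network: the set of (match-set index, match-set index) keys its
    edges map to, for fully covered edges."""
    keys: dict[str, set[tuple[int, int]]] = {}
    for net_id, a, b in nets.edges():
        ia, ib = alignment.index_of(a), alignment.index_of(b)
        if ia is None or ib is None:
            continue
        keys.setdefault(net_id, set()).add((min(ia, ib), max(ia, ib)))
    return keys


def conserved_edges(
    alignment: Alignment, nets: NetworkCollection
) -> tuple[int, list[tuple[str, str, str]]]:
    """Count conserved edges; also return them as (network, a, b)."""
    keys = _edge_keys(nets, alignment)
    conserved: list[tuple[str, str, str]] = []
    for net_id, a, b in nets.edges():
        ia, ib = alignment.index_of(a), alignment.index_of(b)
        if ia is None or ib is None:
            continue
        if ia == ib:  # condition (2): endpoints aligned together
            conserved.append((net_id, a, b))
            continue
        key = (min(ia, ib), max(ia, ib))
        if any(
            key in other_keys
            for other_id, other_keys in keys.items()
            if other_id != net_id
        ):
            conserved.append((net_id, a, b))
    return len(conserved), conserved


def strictly_conserved_edges(
    alignment: Alignment,
    nets: NetworkCollection,
    sim_raw: SimilarityMatrix,
) -> int:
    """Edges with a condition-(1) witness whose two endpoint similarities
    are both positive (one such witness suffices)."""
    count = 0
    for net_id, a, b in nets.edges():
        ia, ib = alignment.index_of(a), alignment.index_of(b)
        if ia is None or ib is None:
            continue
        if _has_strict_witness(a, b, ia, ib, net_id, alignment, nets, sim_raw):
            count += 1
    return count


def _has_strict_witness(
    a: str,
    b: str,
    ia: int,
    ib: int,
    net_id: str,
    alignment: Alignment,
    nets: NetworkCollection,
    sim_raw: SimilarityMatrix,
) -> bool:
    for other_id, x, y in nets.edges():
        if other_id == net_id:
            continue
        ix, iy = alignment.index_of(x), alignment.index_of(y)
        if ix is None or iy is None:
            continue
        for (ax, by) in (((x, y)), ((y, x))):
            if alignment.index_of(ax) == ia and alignment.index_of(by) == ib:
                if sim_raw.get(a, ax) > 0 and sim_raw.get(b, by) > 0:
                    return True
    return False


def coverage_and_rate(
    alignment: Alignment, nets: NetworkCollection
) -> tuple[int, int, float]:
    """(coverage, covered edge count, conserved edge rate).

    Coverage is the number of proteins in any match-set; a covered edge has
    both endpoints covered; the rate is conserved / covered (0 when no edge
    is covered).
    """
    covered = alignment.covered()
    covered_edges = sum(
        1 for _, a, b in nets.edges() if a in covered and b in covered
    )
    n_conserved, _ = conserved_edges(alignment, nets)
    rate = n_conserved / covered_edges if covered_edges else 0.0
    return len(covered), covered_edges, rate


def hypergeom_pvalue(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m) for drawing n
    proteins from N of which M carry the annotation."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise InputFormatError(
            f"inconsistent hypergeometric counts N={N} M={M} n={n} m={m}"
        )
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


@dataclass
class EnrichmentReport:
    """Per-match-set best p-values and the set of enriched GO terms."""

    per_set: list[tuple[float, str | None]]  # (min p-value, best term)
    enriched_terms: set[str]
    alpha: float = ENRICHMENT_ALPHA


def enrichment_report(
    alignment: Alignment,
    annotations: AnnotationMap,
    nets: NetworkCollection,
    *,
    alpha: float = ENRICHMENT_ALPHA,
) -> EnrichmentReport:
    """Hypergeometric GO enrichment of every match-set.

    Each match-set is scored against every term annotating at least one of
    its members and keeps its lowest p-value; a term is enriched when it
    goes below ``alpha`` in at least one match-set.
    """
    N = nets.n
    term_total: dict[str, int] = {}
    for v in nets.vertices:
        for t in annotations.get(v, ()):
            term_total[t] = term_total.get(t, 0) + 1

    per_set: list[tuple[float, str | None]] = []
    enriched: set[str] = set()
    for ms in alignment:
        n = len(ms)
        counts: dict[str, int] = {}
        for v in ms:
            for t in annotations.get(v, ()):
                counts[t] = counts.get(t, 0) + 1
        best_p, best_t = 1.0, None
        for t, m in sorted(counts.items()):
            p = hypergeom_pvalue(N, term_total[t], n, m)
            if p < alpha:
                enriched.add(t)
            if p < best_p:
                best_p, best_t = p, t
        per_set.append((best_p, best_t))
    return EnrichmentReport(per_set, enriched, alpha)


def hungarian_baseline(
    nets: NetworkCollection, sim_raw: SimilarityMatrix
) -> Alignment:
    """One-to-one pairwise alignment maximizing total similarity.

    Only defined for exactly two networks; the optimal assignment is found
    with the Hungarian algorithm and zero-score matches are dropped from
    the output.  This baseline maximizes the average similarity score but
    ignores topology entirely.
    """
    if nets.k != 2:
        raise InputFormatError("Hungarian baseline needs exactly 2 networks")
    va = sorted(nets.networks[0].vertices)
    vb = sorted(nets.networks[1].vertices)
    cost = np.zeros((len(va), len(vb)))
    for i, a in enumerate(va):
        partners = sim_raw.partners(a)
        for j, b in enumerate(vb):
            cost[i, j] = -partners.get(b, 0.0)
    rows, cols = linear_sum_assignment(cost)
    sets = [
        frozenset((va[i], vb[j]))
        for i, j in zip(rows, cols)
        if cost[i, j] < 0
    ]
    return Alignment(sets)


@dataclass
class MetricsReport:
    """All headline metrics of one alignment."""

    average_similarity: float
    conserved_edges: int
    strictly_conserved_edges: int
    coverage: int
    covered_edge_count: int
    conserved_edge_rate: float
    match_set_similarities: list[float] = field(default_factory=list)
    n_match_sets: int = 0

    def as_dict(self) -> dict:
        return {
            "n_match_sets": self.n_match_sets,
            "average_similarity": self.average_similarity,
            "conserved_edges": self.conserved_edges,
            "strictly_conserved_edges": self.strictly_conserved_edges,
            "coverage": self.coverage,
            "covered_edge_count": self.covered_edge_count,
            "conserved_edge_rate": self.conserved_edge_rate,
        }


def compute_metrics(
    alignment: Alignment,
    nets: NetworkCollection,
    sim_raw: SimilarityMatrix,
) -> MetricsReport:
    """Assemble the full metric suite for an alignment (raw scores)."""
    if len(alignment) == 0:
        return MetricsReport(0.0, 0, 0, 0, 0, 0.0, [], 0)
    n_cons, _ = conserved_edges(alignment, nets)
    coverage, covered_edges, rate = coverage_and_rate(alignment, nets)
    return MetricsReport(
        average_similarity=average_similarity(alignment, sim_raw),
        conserved_edges=n_cons,
        strictly_conserved_edges=strictly_conserved_edges(
            alignment, nets, sim_raw
        ),
        coverage=coverage,
        covered_edge_count=covered_edges,
        conserved_edge_rate=rate,
        match_set_similarities=[
            match_set_similarity(ms, sim_raw) for ms in alignment
        ],
        n_match_sets=len(alignment),
    )
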